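"""Cohort I/O: VCF ingest/export, call-set concordance, pipeline driver.

VCF files are read and written through pysam.  Genotypes on the haploid MSY
locus may be encoded haploid ("0"/"1") or homozygous diploid ("0/0"/"1/1");
heterozygous diploid calls are impossible on a haploid locus and are treated
as missing with a warning, matching common MSY practice.  Coordinates are
1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .diversity import MISSING, PopulationSample

__all__ = [
    "CallSet",
    "read_callset",
    "write_callset",
    "read_popmap",
    "read_vcf",
    "population_samples",
    "ConcordanceReport",
    "genotype_concordance",
    "read_sfs",
    "write_sfs",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("msydemog")


@dataclass(frozen=True)
class CallSet:
    """Haploid calls at uniquely keyed sites.

    ``calls`` is (n_sites, n_samples): 0 = reference, k >= 1 = k-th ALT
    allele, -1 = missing.
    """

    samples: tuple[str, ...]
    chrom: tuple[str, ...]
    positions: np.ndarray  # 1-based
    ref: tuple[str, ...]
    alt: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        keys = list(zip(self.chrom, self.positions, self.ref, self.alt))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate site keys")
        if self.calls.shape != (len(self.positions), len(self.samples)):
            raise ValueError("calls matrix shape mismatch")

    @property
    def site_keys(self) -> list[tuple]:
        return list(zip(self.chrom, self.positions, self.ref, self.alt))

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def read_callset(path: str | Path) -> CallSet:
    """Read a haploid (or homozygous-diploid) multi-sample VCF.

    Heterozygous genotypes are collapsed to missing, counted and logged.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = tuple(vcf.header.samples)
        chrom, pos, ref, alt, rows = [], [], [], [], []
        n_het = 0
        for rec in vcf:
            alts = rec.alts or ("N",)
            row = np.full(len(samples), MISSING, dtype=np.int64)
            for j, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    continue
                if len(set(alleles)) > 1:
                    n_het += 1
                    continue
                row[j] = alleles[0]
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alt.append(alts[0])
            rows.append(row)
    if n_het:
        logger.warning("%s: %d heterozygous calls treated as missing", path, n_het)
    return CallSet(
        samples=samples,
        chrom=tuple(chrom),
        positions=np.asarray(pos, dtype=np.int64),
        ref=tuple(ref),
        alt=tuple(alt),
        calls=np.asarray(rows, dtype=np.int64).reshape(len(pos), len(samples)),
    )


def write_callset(cs: CallSet, path: str | Path) -> None:
    """Write a CallSet as a haploid VCF."""
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    max_pos: dict[str, int] = {}
    for c, p in zip(cs.chrom, cs.positions):
        max_pos[c] = max(max_pos.get(c, 0), int(p))
    for c, p in max_pos.items():
        header.contigs.add(c, length=p + 1)
    for s in cs.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(cs.n_sites):
            rec = out.new_record(
                contig=cs.chrom[i],
                start=int(cs.positions[i]) - 1,
                alleles=(cs.ref[i], cs.alt[i]),
            )
            for j, s in enumerate(cs.samples):
                code = int(cs.calls[i, j])
                rec.samples[s]["GT"] = (None,) if code == MISSING else (code,)
            out.write(rec)


def read_popmap(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, population id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    return dict(zip(df["sample"], df["pop"]))


def population_samples(
    cs: CallSet, popmap: dict[str, str]
) -> dict[str, PopulationSample]:
    """Split a CallSet into per-population haploid samples.

    Samples missing from the popmap are dropped with a warning; popmap
    entries referencing absent samples are an error.
    """
    absent = sorted(set(popmap) - set(cs.samples))
    if absent:
        raise ValueError(f"popmap references absent samples: {absent}")
    unassigned = [s for s in cs.samples if s not in popmap]
    if unassigned:
        logger.warning("dropping %d samples without population assignment", len(unassigned))
    pops: dict[str, list[int]] = {}
    for j, s in enumerate(cs.samples):
        if s in popmap:
            pops.setdefault(popmap[s], []).append(j)
    return {
        pop: PopulationSample(
            pop_id=pop,
            individuals=tuple(cs.samples[j] for j in idx),
            positions=cs.positions.copy(),
            calls=cs.calls[:, idx].copy(),
        )
        for pop, idx in sorted(pops.items())
    }


def read_vcf(path: str | Path, popmap: dict[str, str] | str | Path) -> dict[str, PopulationSample]:
    """Read a VCF and split it by population (popmap: dict or TSV path)."""
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    return population_samples(read_callset(path), popmap)


@dataclass(frozen=True)
class ConcordanceReport:
    n_overlap_sites: int
    n_overlap_samples: int
    n_comparable: int
    false_positive_rate: float  # percent: variant in a, reference in b
    false_negative_rate: float  # percent: reference in a, variant in b
    discordant_sites: tuple[tuple, ...]


def genotype_concordance(a: CallSet, b: CallSet) -> ConcordanceReport:
    """Compare two call sets over their shared samples and site keys.

    Rates are percentages of comparable (both non-missing) calls: a false
    positive is a variant call in ``a`` where ``b`` has reference, a false
    negative the converse.
    """
    shared_samples = [s for s in a.samples if s in set(b.samples)]
    keys_a = {k: i for i, k in enumerate(a.site_keys)}
    keys_b = {k: i for i, k in enumerate(b.site_keys)}
    shared_keys = [k for k in keys_a if k in keys_b]
    if not shared_samples or not shared_keys:
        raise ValueError("call sets share no samples or no sites")
    ja = [a.samples.index(s) for s in shared_samples]
    jb = [b.samples.index(s) for s in shared_samples]
    ga = a.calls[np.ix_([keys_a[k] for k in shared_keys], ja)]
    gb = b.calls[np.ix_([keys_b[k] for k in shared_keys], jb)]
    ok = (ga != MISSING) & (gb != MISSING)
    fp = (ga > 0) & (gb == 0) & ok
    fn = (ga == 0) & (gb > 0) & ok
    n_cmp = int(ok.sum())
    if n_cmp == 0:
        raise ValueError("no comparable calls")
    discordant = [shared_keys[i] for i in np.where((fp | fn).any(axis=1))[0]]
    return ConcordanceReport(
        n_overlap_sites=len(shared_keys),
        n_overlap_samples=len(shared_samples),
        n_comparable=n_cmp,
        false_positive_rate=100.0 * fp.sum() / n_cmp,
        false_negative_rate=100.0 * fn.sum() / n_cmp,
        discordant_sites=tuple(discordant),
    )


def read_sfs(path: str | Path) -> np.ndarray:
    """Observed SFS as TSV (category, count) -> counts xi_1..xi_{n-1}."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(df.columns[0])
    cats = df.iloc[:, 0].to_numpy(dtype=int)
    if not np.array_equal(cats, np.arange(1, len(cats) + 1)):
        raise ValueError("SFS categories must be 1..n-1 without gaps")
    return df.iloc[:, 1].to_numpy(dtype=float)


def write_sfs(counts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"category": np.arange(1, len(counts) + 1), "count": counts}
    ).to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """Configuration of an end-to-end run; YAML-serialisable.

    Every stochastic stage derives its substream from ``seed``; the
    ``full_size`` switch exists so the scaled-down defaults can be raised
    to production counts without code changes.
    """

    seed: int
    out_dir: str
    n: int = 20
    models: tuple[str, ...] = ("M1", "M4")
    n_sims: int = 1000
    n_accept: int = 100
    observed_sfs: str | None = None
    vcf: str | None = None
    popmap: str | None = None
    null_sims: int = 200
    full_size: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> (stats, abc) -> manifest as configured.

    Writes one reference table per model, optionally a diversity table
    (when a VCF and popmap are given) and ABC fits (when an observed SFS
    is given), plus a JSON manifest holding seeds, settings and sha256
    digests of every input and output, sufficient to reproduce the run.
    """
    from . import __version__
    from .abcfit import (
        build_summary,
        local_linear_adjust,
        model_choice_logistic,
        reject,
        sfs_columns,
    )
    from .coalescent import simulate_batch, write_reference_table
    from .demography import model_spec
    from .diversity import diversity_table

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "package": "msydemog",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "stages": [],
        "inputs": {},
        "outputs": {},
    }
    for key in ("observed_sfs", "vcf", "popmap"):
        p = getattr(config, key)
        if p:
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} input not found: {p}")
            manifest["inputs"][key] = _sha256(Path(p))

    ss = np.random.SeedSequence(config.seed)
    sim_seed, stats_seed, abc_seed = ss.spawn(3)

    tables = {}
    for mid, child in zip(config.models, sim_seed.spawn(len(config.models))):
        spec = model_spec(mid)
        tbl = simulate_batch(spec, config.n_sims, config.n, child)
        path = out / f"ref_{mid}.tsv"
        write_reference_table(tbl, str(path))
        tables[mid] = tbl
        manifest["outputs"][path.name] = _sha256(path)
        manifest["stages"].append(
            {"stage": "simulate", "model": mid, "rows": len(tbl)}
        )
        logger.info("simulate %s: %d rows", mid, len(tbl))

    if config.vcf and config.popmap:
        samples = read_vcf(config.vcf, config.popmap)
        dt = diversity_table(
            list(samples.values()), config.null_sims, int(stats_seed.generate_state(1)[0] % 2**31)
        )
        path = out / "diversity.tsv"
        dt.to_csv(path, sep="\t", index=False)
        manifest["outputs"][path.name] = _sha256(path)
        manifest["stages"].append({"stage": "stats", "populations": len(dt)})

    if config.observed_sfs:
        obs_counts = read_sfs(config.observed_sfs)
        combined = pd.concat(tables.values(), ignore_index=True)
        obs, sims, _ = build_summary(obs_counts, combined)
        rng = np.random.default_rng(abc_seed)
        probs = model_choice_logistic(
            obs, sims, combined["model"].to_numpy(), config.n_accept, rng
        )
        probs.rename("probability").to_csv(out / "model_posterior.tsv", sep="\t")
        best = str(probs.idxmax())
        spec = model_spec(best)
        tbl = tables[best]
        obs_b, sims_b, _ = build_summary(obs_counts, tbl)
        res = reject(obs_b, sims_b, min(config.n_accept, len(tbl)), rng)
        post = local_linear_adjust(
            tbl.iloc[res.indices][list(spec.parameter_names)],
            sims_b[res.indices],
            res.distances,
            res.tolerance,
            obs_b,
            spec.priors,
        )
        rows = [
            {
                "parameter": p.name,
                "median": p.median,
                "mode": p.mode,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "r2": p.r2,
                "adjusted": p.adjusted,
            }
            for p in post.values()
        ]
        path = out / "parameter_posterior.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        for name in ("model_posterior.tsv", "parameter_posterior.tsv"):
            manifest["outputs"][name] = _sha256(out / name)
        manifest["stages"].append({"stage": "abc", "best_model": best})

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
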