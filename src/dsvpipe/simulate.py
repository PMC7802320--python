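"""Synthetic cohorts with planted, recoverable structure.

The generator emulates a case/control germline deletion study: diploid
genotypes drawn under Hardy–Weinberg equilibrium per cohort, case-enriched
deletions planted at requested carrier odds ratios, immune-gene expression
linearly coupled to chosen carrier indicators, and recurrence-free survival
from a proportional-hazards model with exponential baseline hazard.  Every
downstream estimator in the pipeline therefore has a parameter-recovery
oracle with known truth.

Randomness is fully determined by ``SimulationConfig.seed``; each stage
draws from a substream spawned deterministically from that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import CarrierMatrix, DeletionRecord, MISSING, build_carrier_matrix

#: the six immune-function categories of the expression panel
IMMUNE_CATEGORIES = (
    "housekeeping",
    "checkpoint pathways",
    "cytokine signaling",
    "lymphocyte markers",
    "lymphocyte regulation",
    "tumor characterization",
)

CANCER_TYPES = ("colorectal", "endometrial", "ovarian", "breast")
_CANCER_TYPE_P = (120 / 192, 29 / 192, 35 / 192, 8 / 192)


@dataclass(frozen=True)
class PlantedRisk:
    dsv_index: int
    odds_ratio: float       # case/control odds ratio on carrier status
    control_allele_freq: float


@dataclass(frozen=True)
class PlantedExpression:
    dsv_index: int
    gene_index: int
    beta: float             # linear effect of carrier status on expression
    sigma: float            # residual (noise) standard deviation


@dataclass(frozen=True)
class PlantedHazard:
    dsv_index: int
    log_hr: float


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 192 cancer patients vs 499
    non-cancer subjects, family cancer history present in ~43.5% of the
    non-cancer cohort and enriched in cases at odds ratio 1.89, deletions
    500–10,000 bp on autosomes.  Time is measured in months; the baseline
    recurrence hazard of 0.02/month and censoring of 0.01/month give
    median event times of a few years under a ~null genotype.
    """

    n_cancer: int = 192
    n_control: int = 499
    m_background: int = 100
    planted_risk: Sequence[PlantedRisk] = ()
    planted_expression: Sequence[PlantedExpression] = ()
    planted_hazard: Sequence[PlantedHazard] = ()
    background_freq_range: tuple[float, float] = (0.05, 0.35)
    baseline_hazard: float = 0.02       # events per month
    censor_rate: float = 0.01           # censorings per month
    fch_odds_ratio: float = 1.89
    fch_control_prevalence: float = 0.435
    n_genes: int = 40
    n_categories: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cancer, self.n_control, self.m_background, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.background_freq_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("background allele frequencies must lie in (0, 0.5]")
        for pr in self.planted_risk:
            if not (0 < pr.control_allele_freq <= 0.5):
                raise ValueError("planted control allele frequency must lie in (0, 0.5]")
            if pr.odds_ratio <= 0:
                raise ValueError("odds ratios must be positive")
        for pe in self.planted_expression:
            if pe.sigma <= 0:
                raise ValueError("expression noise sigma must be positive")
            if not (0 <= pe.gene_index < self.n_genes):
                raise ValueError("planted gene index out of range")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor rate must be non-negative")
        if self.fch_odds_ratio <= 0:
            raise ValueError("FCH odds ratio must be positive")
        if self.n_categories != 6:
            raise ValueError("the immune panel uses exactly 6 categories")

    @property
    def m_total(self) -> int:
        return self.m_background + len(self.planted_risk)


@dataclass
class SyntheticTruth:
    """Planted structure, for parameter-recovery tests."""

    risk_dsv_ids: list[str]
    expression_pairs: list[tuple[str, str]]      # (dsv_id, gene_id)
    hazard_dsvs: list[tuple[str, float]]         # (dsv_id, log hazard ratio)
    allele_freqs: pd.DataFrame                   # dsv_id, cancer_freq, control_freq
    dsv_ids: list[str] = field(default_factory=list)


def _case_carrier_freq(odds_ratio: float, control_allele_freq: float) -> float:
    """Case carrier probability implied by a carrier odds ratio under HWE."""
    c0 = 1 - (1 - control_allele_freq) ** 2
    odds1 = odds_ratio * c0 / (1 - c0)
    c1 = odds1 / (1 + odds1) if np.isfinite(odds1) else 1.0
    if c1 >= 1:
        raise ValueError(
            f"odds ratio {odds_ratio} at control frequency {control_allele_freq} "
            "implies a case carrier frequency >= 1"
        )
    return c1


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[list[DeletionRecord], pd.DataFrame, SyntheticTruth]:
    """Draw deletion genotypes and the cohort table.

    Background DSVs share one Hardy–Weinberg allele frequency across both
    cohorts; each planted risk DSV gets a case allele frequency solved from
    the requested carrier odds ratio.  Coordinates are uniform on the 22
    autosomes with lengths uniform on [500, 10000] bp.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_coord, rng_cohort = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_case, n_ctrl = config.n_cancer, config.n_control
    n = n_case + n_ctrl
    m = config.m_total
    planted_idx = {pr.dsv_index for pr in config.planted_risk}
    if len(planted_idx) != len(config.planted_risk):
        raise ValueError("planted risk dsv indices must be unique")
    if planted_idx and (max(planted_idx) >= m or min(planted_idx) < 0):
        raise ValueError("planted risk dsv index out of range")

    lo, hi = config.background_freq_range
    case_freq = np.empty(m)
    ctrl_freq = np.empty(m)
    bg_cols = [j for j in range(m) if j not in planted_idx]
    bg_freqs = rng_geno.uniform(lo, hi, size=len(bg_cols))
    for j, f in zip(bg_cols, bg_freqs):
        case_freq[j] = ctrl_freq[j] = f
    for pr in config.planted_risk:
        c1 = _case_carrier_freq(pr.odds_ratio, pr.control_allele_freq)
        q1 = 1 - np.sqrt(1 - c1)  # allele freq with carrier prob c1 under HWE
        case_freq[pr.dsv_index] = q1
        ctrl_freq[pr.dsv_index] = pr.control_allele_freq

    geno = np.empty((n, m), dtype=np.int8)
    geno[:n_case] = rng_geno.binomial(2, case_freq, size=(n_case, m))
    geno[n_case:] = rng_geno.binomial(2, ctrl_freq, size=(n_ctrl, m))

    chroms = rng_coord.integers(1, 23, size=m)
    lengths = rng_coord.integers(500, 10_001, size=m)
    starts = rng_coord.integers(1_000_000, 100_000_000, size=m)
    dsv_ids = [f"DSV{j:05d}" for j in range(m)]
    records = [
        DeletionRecord(
            dsv_id=dsv_ids[j],
            chromosome=f"chr{chroms[j]}",
            start=int(starts[j]),
            end=int(starts[j] + lengths[j]),
            genotypes=geno[:, j],
        )
        for j in range(m)
    ]

    sample_ids = [f"S{i:04d}" for i in range(n)]
    labels = ["cancer"] * n_case + ["non-cancer"] * n_ctrl
    p0 = config.fch_control_prevalence
    odds1 = config.fch_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    fch_p = np.where(np.arange(n) < n_case, p1, p0)
    fch = np.where(rng_cohort.uniform(size=n) < fch_p, "yes", "no")
    cancer_type = np.where(
        np.arange(n) < n_case,
        rng_cohort.choice(CANCER_TYPES, size=n, p=_CANCER_TYPE_P),
        "none",
    )
    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort_label": labels,
            "fch": fch,
            "sex": rng_cohort.choice(["male", "female"], size=n),
            "age": rng_cohort.integers(30, 75, size=n),
            "cancer_type": cancer_type,
            "recurrence": "not-applicable",
            "rfs_time": np.nan,
            "rfs_event": np.nan,
        }
    )

    emp_case = geno[:n_case].astype(float).sum(axis=0) / (2 * n_case)
    emp_ctrl = geno[n_case:].astype(float).sum(axis=0) / (2 * n_ctrl)
    truth = SyntheticTruth(
        risk_dsv_ids=[dsv_ids[pr.dsv_index] for pr in config.planted_risk],
        expression_pairs=[
            (dsv_ids[pe.dsv_index], f"G{pe.gene_index:04d}")
            for pe in config.planted_expression
        ],
        hazard_dsvs=[(dsv_ids[ph.dsv_index], ph.log_hr) for ph in config.planted_hazard],
        allele_freqs=pd.DataFrame(
            {"dsv_id": dsv_ids, "cancer_freq": emp_case, "control_freq": emp_ctrl}
        ),
        dsv_ids=dsv_ids,
    )
    return records, cohort, truth


def simulate_expression(carriers: CarrierMatrix, config: SimulationConfig):
    """Immune-panel expression: standard-normal noise, plus ``beta * carrier``
    for each planted (DSV, gene) pair.  Genes get the six functional
    categories round-robin."""
    from .immune import ExpressionMatrix

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[-1])
    gene_ids = [f"G{g:04d}" for g in range(config.n_genes)]
    samples = carriers.sample_ids
    values = rng.normal(0.0, 1.0, size=(config.n_genes, len(samples)))
    for pe in config.planted_expression:
        dsv_id = carriers.dsv_ids[pe.dsv_index]
        x = carriers.data[dsv_id].to_numpy(dtype=float)
        values[pe.gene_index] = pe.beta * x + rng.normal(0.0, pe.sigma, size=len(samples))
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
    categories = pd.Series(
        [IMMUNE_CATEGORIES[g % 6] for g in range(config.n_genes)],
        index=df.index,
        name="category",
    )
    return ExpressionMatrix(values=df, categories=categories, normalized=False)


def simulate_survival(
    carriers: CarrierMatrix, config: SimulationConfig, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fill recurrence-free-survival columns from a proportional-hazards draw.

    Event times are exponential with rate ``baseline_hazard *
    exp(sum log_hr * carrier)``; censoring is an independent exponential.
    Returns a cohort table (a copy when one is supplied) with ``rfs_time``,
    ``rfs_event`` and ``recurrence`` set for every sample in ``carriers``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[-1])
    samples = carriers.sample_ids
    n = len(samples)
    lin = np.zeros(n)
    for ph in config.planted_hazard:
        dsv_id = carriers.dsv_ids[ph.dsv_index]
        lin += ph.log_hr * carriers.data[dsv_id].to_numpy(dtype=float)
    rate = config.baseline_hazard * np.exp(lin)
    event_t = rng.exponential(1.0 / rate)
    if config.censor_rate == 0:
        censor_t = np.full(n, np.inf)
    elif np.isinf(config.censor_rate):
        censor_t = np.zeros(n)
    else:
        censor_t = rng.exponential(1.0 / config.censor_rate, size=n)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    if cohort is None:
        cohort = pd.DataFrame(
            {
                "sample_id": samples,
                "cohort_label": "cancer",
                "fch": "unknown",
                "sex": "unknown",
                "age": np.nan,
                "cancer_type": "colorectal",
                "recurrence": "not-applicable",
                "rfs_time": np.nan,
                "rfs_event": np.nan,
            }
        )
    out = cohort.copy()
    missing = set(samples) - set(out["sample_id"])
    if missing:
        raise ValueError(f"carrier-matrix samples absent from cohort: {sorted(missing)[:5]}")
    tmap = dict(zip(samples, time))
    emap = dict(zip(samples, event))
    mask = out["sample_id"].isin(tmap).to_numpy()
    sid = out.loc[mask, "sample_id"]
    out.loc[mask, "rfs_time"] = sid.map(tmap).to_numpy()
    out.loc[mask, "rfs_event"] = sid.map(emap).to_numpy(dtype=float)
    out.loc[mask, "recurrence"] = np.where(sid.map(emap).to_numpy() == 1, "yes", "no")
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_deletions_vcf(
    records: Sequence[DeletionRecord], sample_ids: Sequence[str], path: str | Path
) -> None:
    """Write deletion records as a minimal VCF 4.2 with per-sample GT."""
    lines = [_VCF_HEADER]
    for chrom in sorted({r.chromosome for r in records}):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
        + "\n"
    )
    for rec in records:
        gts = "\t".join(_GT_STRING[int(g)] for g in rec.genotypes)
        lines.append(
            f"{rec.chromosome}\t{rec.start}\t{rec.dsv_id}\tN\t<DEL>\t.\tPASS\t"
            f"SVTYPE=DEL;END={rec.end}\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


def gene_models_for(records: Sequence[DeletionRecord], margin: int = 1000) -> pd.DataFrame:
    """Synthetic gene models: one gene spanning each DSV (+/- margin), BED coords."""
    return pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in records],
            "start": [max(0, r.start - 1 - margin) for r in records],
            "end": [r.end - 1 + margin for r in records],
            "name": [f"GENE_{r.dsv_id}" for r in records],
        }
    )


def write_fixture_bundle(
    out_dir: str | Path,
    records: Sequence[DeletionRecord],
    cohort: pd.DataFrame,
    expression=None,
    gene_bed: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write VCF + cohort TSV (+ optional expression TSVs and gene BED).

    The files round-trip losslessly through the readers of
    :mod:`dsvpipe.preprocess`.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["vcf"] = out_dir / "deletions.vcf"
    write_deletions_vcf(records, list(cohort["sample_id"]), paths["vcf"])
    paths["cohort"] = out_dir / "cohort.tsv"
    cohort.to_csv(paths["cohort"], sep="\t", index=False)
    if expression is not None:
        paths["expression"] = out_dir / "expression.tsv"
        expression.values.to_csv(paths["expression"], sep="\t")
        paths["categories"] = out_dir / "gene_categories.tsv"
        expression.categories.to_frame().to_csv(paths["categories"], sep="\t")
    if gene_bed is None:
        gene_bed = gene_models_for(records)
    paths["genes"] = out_dir / "genes.bed"
    gene_bed.to_csv(paths["genes"], sep="\t", header=False, index=False)
    return paths


def carrier_matrix_from_truth(records, cohort) -> CarrierMatrix:
    """Convenience: the simulator's own carrier matrix (genotype >= 1)."""
    return build_carrier_matrix(records, cohort)
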