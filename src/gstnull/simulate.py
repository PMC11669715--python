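"""Ground-truthed synthetic tumor cohorts.

Generates cohorts with the statistical structure the analysis assumes so
every pipeline stage is testable without external downloads:

* germline deletion polymorphism of one GST gene under Hardy-Weinberg
  equilibrium at a configurable null-allele frequency;
* somatic single-arm loss that removes one uniformly chosen haplotype
  (taking the non-polymorphic neighbor gene's copy with it);
* copy-dosage-proportional expression with multiplicative lognormal noise
  (zero copies -> exactly zero transcript);
* qPCR plates whose Ct values follow per-assay log-linear standard curves
  with Gaussian replicate noise, plus plasmid dilution series;
* a two-group expression matrix with a planted differentially expressed
  gene set and a pair of anti-linked marker programs.

All stages draw from independent streams spawned from one seed, so a
bundle is bit-for-bit reproducible and stages can be rerun in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, GstPanelTable, PANEL_GENES
from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticCohortBundle",
    "simulate_germline_genotypes",
    "simulate_somatic_events",
    "simulate_expression",
    "simulate_qpcr",
    "generate_cohort",
    "DEFAULT_CURVE_PARAMS",
]

#: Per-assay log-linear curve parameters (perfect doubling: slope -3.3219).
DEFAULT_CURVE_PARAMS: Mapping[str, tuple[float, float]] = {
    gene: (-3.321928094887362, 40.0)
    for gene in (*PANEL_GENES, "APOB", "GAPDH")
}

#: Absolute plasmid quantity (copies/reaction) contributed by one gene copy.
QUANTITY_PER_COPY = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for cohort generation.

    Defaults model the studied tumor subtype: every tumor carries the
    somatic arm loss (``p_somatic_arm_loss=1``) and recurrence is fully
    linked to the final null genotype (``recurrence_null_enrichment=1``),
    matching a cohort where all recurrent tumors lack the polymorphic
    gene. ``null_allele_freq=0.5`` is a testing default for the germline
    polymorphism, not a population estimate.
    """

    seed: int = 0
    n_primary: int = 12
    n_recurrent: int = 4
    null_allele_freq: float = 0.5
    p_somatic_arm_loss: float = 1.0
    p_second_loss: float = 0.0
    per_copy_expression: float = 25.0
    expression_noise_cv: float = 0.2
    ct_noise_sd: float = 0.15
    n_ct_replicates: int = 3
    curve_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CURVE_PARAMS)
    )
    n_genes: int = 500
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    recurrence_null_enrichment: float = 1.0

    def validate(self) -> None:
        problems = []
        for name in (
            "null_allele_freq",
            "p_somatic_arm_loss",
            "p_second_loss",
            "de_fraction",
            "recurrence_null_enrichment",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        if not (1 <= self.n_ct_replicates <= 6):
            problems.append(f"n_ct_replicates={self.n_ct_replicates} outside [1, 6]")
        if self.n_primary < 0 or self.n_recurrent < 0:
            problems.append("group sizes must be nonnegative")
        if self.ct_noise_sd < 0:
            problems.append("ct_noise_sd must be >= 0")
        if self.expression_noise_cv < 0:
            problems.append("expression_noise_cv must be >= 0")
        for assay, (slope, _) in self.curve_params.items():
            if slope >= 0:
                problems.append(f"curve slope for {assay} must be negative")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class SyntheticCohortBundle:
    """Ground truth plus every derived observable for one simulated cohort."""

    config: SimulationConfig
    truth: pd.DataFrame  # per-tumor germline haplotypes, losses, true copies
    cohort: CohortTable
    panel: GstPanelTable
    plates: pd.DataFrame  # well, sample_id, assay, reporter, ct ('' = undetected)
    dilution_series: dict[str, pd.DataFrame]  # assay -> known_quantity, ct
    expression: ExpressionMatrix


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_germline_genotypes(
    config: SimulationConfig, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Germline haplotype pairs under HWE.

    Returns an (n, 2) boolean array: True where a haplotype carries the
    present (functional) allele of the polymorphic gene. Each haplotype is
    null independently with probability ``null_allele_freq``, which yields
    HWE genotype frequencies q^2 / 2q(1-q) / (1-q)^2.
    """
    if n is None:
        n = config.n_primary + config.n_recurrent
    return rng.random((n, 2)) >= config.null_allele_freq


def simulate_somatic_events(
    haplotypes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Somatic arm loss on germline haplotypes.

    With probability ``p_somatic_arm_loss`` a tumor loses exactly one
    haplotype, chosen uniformly; with ``p_second_loss`` (conditional on the
    first) it also loses the other, producing the double-somatic-loss
    configuration. The neighbor gene is present on every haplotype, so its
    tumor copy number is the number of surviving haplotypes.
    """
    n = len(haplotypes)
    lost1 = rng.random(n) < config.p_somatic_arm_loss
    which = rng.integers(0, 2, size=n)
    lost2 = lost1 & (rng.random(n) < config.p_second_loss)
    surviving = np.ones((n, 2), dtype=bool)
    surviving[lost1, which[lost1]] = False
    surviving[lost2] = False
    poly_copies = (haplotypes & surviving).sum(axis=1)
    neighbor_copies = surviving.sum(axis=1)
    return pd.DataFrame(
        {
            "germline_hap1_present": haplotypes[:, 0],
            "germline_hap2_present": haplotypes[:, 1],
            "germline_copies": haplotypes.sum(axis=1),
            "somatic_loss": lost1,
            "lost_haplotype": np.where(lost1, which, -1),
            "second_loss": lost2,
            "poly_copies": poly_copies,
            "neighbor_copies": neighbor_copies,
        }
    )


def simulate_expression(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    groups: Sequence[str],
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Dosage-proportional panel expression plus a background matrix.

    Panel genes: expression = copies * per_copy_expression * lognormal
    noise with the configured CV; zero copies give exactly zero (no leaky
    transcription). Background genes are lognormal with a planted
    ``de_fraction`` shifted by ``de_log2fc`` in the second group, plus two
    marker program genes ("GSTM1" dosage-linked, "MAP1LC3C" elevated in
    null tumors only) supporting mutual-exclusivity tests.
    """
    n = len(truth)
    sample_ids = truth["sample_id"].tolist()
    sigma = np.sqrt(np.log1p(config.expression_noise_cv**2))

    def dosage(copies: np.ndarray) -> np.ndarray:
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(copies)))
        return np.where(copies > 0, copies * config.per_copy_expression * noise, 0.0)

    panel_expr = {
        "poly_expr": dosage(truth["poly_copies"].to_numpy()),
        "neighbor_expr": dosage(truth["neighbor_copies"].to_numpy()),
    }

    # background matrix (FPKM-like lognormal), planted DE block
    base = rng.lognormal(mean=3.0, sigma=1.0, size=config.n_genes)
    X = base[:, None] * np.exp(
        rng.normal(-sigma**2 / 2, sigma, size=(config.n_genes, n))
    )
    n_de = int(round(config.de_fraction * config.n_genes))
    is_b = np.array([g == "recurrent" for g in groups])
    X[:n_de][:, is_b] *= 2.0**config.de_log2fc
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    null_mask = (truth["poly_copies"] == 0).to_numpy()
    gstm1_row = panel_expr["poly_expr"]
    # anti-linked marker: high in null tumors, low otherwise -> never low/low
    map1lc3c_row = np.where(null_mask, 80.0, 5.0) * np.exp(
        rng.normal(-sigma**2 / 2, sigma, size=n)
    )
    gapdh_row = np.full(n, 1000.0)

    values = pd.DataFrame(
        np.vstack([X, gstm1_row, map1lc3c_row, gapdh_row]),
        index=genes + ["GSTM1", "MAP1LC3C", "GAPDH"],
        columns=sample_ids,
    )
    matrix = ExpressionMatrix(
        values=values, unit="FPKM", groups=dict(zip(sample_ids, groups))
    )
    return pd.DataFrame(panel_expr, index=truth.index), matrix


def simulate_qpcr(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    poly_gene: str = "GSTM1",
    neighbor_gene: str = "GSTM2",
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """qPCR plate rows and per-assay plasmid dilution series.

    Per reaction the input quantity is proportional to the true copy
    number (the APOB reference contributes exactly 2 copies); Ct follows
    the assay's log-linear curve with Gaussian noise of ``ct_noise_sd``,
    replicated ``n_ct_replicates`` times. Zero copies yield undetected
    wells (empty ct fields).
    """
    rows = []
    copy_cols = {poly_gene: "poly_copies", neighbor_gene: "neighbor_copies", "APOB": None}

    def ct_for(assay: str, quantity: float, n_rep: int) -> list[str]:
        slope, intercept = config.curve_params[assay]
        if quantity <= 0:
            return [""] * n_rep
        base = intercept + slope * np.log10(quantity)
        return [
            format(base + rng.normal(0.0, config.ct_noise_sd), ".6f")
            for _ in range(n_rep)
        ]

    well = 0
    for _, row in truth.iterrows():
        for assay, col in copy_cols.items():
            copies = 2 if col is None else int(row[col])
            for ct in ct_for(assay, copies * QUANTITY_PER_COPY, config.n_ct_replicates):
                rows.append(
                    {
                        "well": f"W{well:04d}",
                        "sample_id": row["sample_id"],
                        "assay": assay,
                        "reporter": "VIC" if assay == "APOB" else "FAM",
                        "ct": ct,
                    }
                )
                well += 1
    plates = pd.DataFrame(rows)

    series: dict[str, pd.DataFrame] = {}
    dilution_qs = 10.0 ** np.arange(1, 6)  # 5-point 10-fold series
    for assay in copy_cols:
        srows = []
        for q in dilution_qs:
            for ct in ct_for(assay, q, config.n_ct_replicates):
                srows.append({"known_quantity": q, "ct": float(ct)})
        series[assay] = pd.DataFrame(srows)
    return plates, series


def _draw_tumor(
    config: SimulationConfig,
    rng: np.random.Generator,
    require_null: bool,
    max_attempts: int = 10_000,
) -> pd.Series:
    for _ in range(max_attempts):
        hap = simulate_germline_genotypes(config, rng, n=1)
        t = simulate_somatic_events(hap, config, rng).iloc[0]
        if not require_null or t["poly_copies"] == 0:
            return t
    raise RuntimeError(
        "could not draw a null-genotype tumor; null_allele_freq and "
        "p_somatic_arm_loss make the null genotype (near-)impossible"
    )


def generate_cohort(
    config: SimulationConfig,
    *,
    poly_gene: str = "GSTM1",
    neighbor_gene: str = "GSTM2",
) -> SyntheticCohortBundle:
    """Compose a fully consistent synthetic cohort bundle.

    Recurrent tumors are drawn conditional on the final null genotype with
    probability ``recurrence_null_enrichment`` (rejection sampling over the
    germline x somatic process), mirroring the observation that recurrence
    tracks the null genotype in the modeled subtype.
    """
    config.validate()
    rng_geno, rng_expr, rng_qpcr, rng_clin = _streams(config.seed, 4)

    records = []
    groups = ["primary"] * config.n_primary + ["recurrent"] * config.n_recurrent
    for i, group in enumerate(groups):
        require_null = (
            group == "recurrent"
            and rng_geno.random() < config.recurrence_null_enrichment
        )
        t = _draw_tumor(config, rng_geno, require_null)
        t["sample_id"] = f"S{i + 1:03d}"
        t["group"] = group
        records.append(t)
    truth = pd.DataFrame(records).reset_index(drop=True)

    panel_expr, matrix = simulate_expression(truth, config, rng_expr, groups)
    plates, series = simulate_qpcr(
        truth, config, rng_qpcr, poly_gene=poly_gene, neighbor_gene=neighbor_gene
    )

    # untyped panel genes (the other GST pair) default to 2 copies / silent
    panel_rows = []
    for i, row in truth.iterrows():
        d = {"sample_id": row["sample_id"]}
        for g in PANEL_GENES:
            if g == poly_gene:
                d[f"{g}_copy"] = int(row["poly_copies"])
                d[f"{g}_expr_x1000"] = round(float(panel_expr.loc[i, "poly_expr"]), 2)
            elif g == neighbor_gene:
                d[f"{g}_copy"] = int(row["neighbor_copies"])
                d[f"{g}_expr_x1000"] = round(
                    float(panel_expr.loc[i, "neighbor_expr"]), 2
                )
            else:
                d[f"{g}_copy"] = 2
                d[f"{g}_expr_x1000"] = 0.0
        panel_rows.append(d)
    panel = GstPanelTable(pd.DataFrame(panel_rows))

    ages = np.clip(rng_clin.normal(62, 13, size=len(truth)).round(), 20, 95).astype(int)
    rins = np.round(rng_clin.uniform(7.0, 10.0, size=len(truth)), 1)
    cohort = CohortTable(
        pd.DataFrame(
            {
                "sample_id": truth["sample_id"],
                "patient_id": [f"P{i + 1:03d}" for i in range(len(truth))],
                "group": truth["group"],
                "sex": rng_clin.choice(["F", "M"], size=len(truth)),
                "age_years": ages,
                "who_grade": rng_clin.choice([1, 2, 3], size=len(truth), p=[0.5, 0.4, 0.1]),
                "histology": "Simulated",
                "ki67_text": rng_clin.integers(1, 13, size=len(truth)).astype(str),
                "rin": rins,
                "mutated_genes": "NF2",
                "chr22_loss": "Loss of chr 22",
                "chr1p_loss": np.where(
                    truth["somatic_loss"], "Loss of 1p36.33p11.2", "No loss detected"
                ),
            }
        )
    )
    return SyntheticCohortBundle(
        config=config,
        truth=truth,
        cohort=cohort,
        panel=panel,
        plates=plates,
        dilution_series=series,
        expression=matrix,
    )
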