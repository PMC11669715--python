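"""Re-run every desk-reproducible cohort result from the packaged fixtures.

Each check recomputes one quantity from the shipped 16-tumor tables with
the package's own operations and compares it against the published value
(exact for integer counts and medians, small absolute tolerances for
floating-point statistics). Intended both as an install self-test and as a
regression guard for the analysis chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cohort import load_cohort_fixture, load_gst_panel_fixture, summarize_cohort
from .expression import dosage_analysis, pearson_with_ci
from .genotype import GSTM1_SCHEME, GSTT1_SCHEME, genotype_cohort

__all__ = ["ReproCheck", "ReproReport", "run_reproduction"]


@dataclass(frozen=True)
class ReproCheck:
    check_id: str
    description: str
    expected: float
    computed: float
    tolerance: float  # 0 means exact
    passed: bool


@dataclass
class ReproReport:
    checks: list[ReproCheck] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall_pass": self.overall_pass,
                "checks": [c.__dict__ for c in self.checks],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"{'check':28s} {'expected':>10s} {'computed':>10s} {'tol':>8s} pass"
        ]
        for c in self.checks:
            lines.append(
                f"{c.check_id:28s} {c.expected:>10.4f} {c.computed:>10.4f} "
                f"{c.tolerance:>8.4f} {'yes' if c.passed else 'NO'}"
            )
        lines.append(f"overall: {'PASS' if self.overall_pass else 'FAIL'}")
        return "\n".join(lines)


def _check(
    report: ReproReport,
    check_id: str,
    description: str,
    expected: float,
    computed: float,
    tolerance: float = 0.0,
) -> None:
    passed = (
        computed == expected
        if tolerance == 0
        else abs(computed - expected) <= tolerance
    )
    report.checks.append(
        ReproCheck(check_id, description, float(expected), float(computed), tolerance, passed)
    )


def run_reproduction() -> ReproReport:
    """Recompute the published cohort-level numbers from the fixtures."""
    cohort = load_cohort_fixture()
    panel = load_gst_panel_fixture()
    groups = cohort.data.set_index("sample_id")["group"]
    report = ReproReport()

    # --- GSTM1 expression partition among primary tumors ---
    gstm1_expr = panel.expression("GSTM1")
    primary = groups[groups == "primary"].index
    n_zero = int((gstm1_expr[primary] == 0).sum())
    _check(report, "primary_gstm1_zero", "primary tumors without GSTM1 expression", 5, n_zero)
    _check(
        report,
        "primary_gstm1_expressed",
        "primary tumors with GSTM1 expression",
        7,
        len(primary) - n_zero,
    )

    # --- copy-number counts ---
    gstm2 = panel.copies("GSTM2")
    homo = gstm2[gstm2 == 2].index
    _check(report, "gstm2_homozygous", "tumors with two GSTM2 copies", 4, len(homo))
    _check(
        report,
        "gstm2_homozygous_recurrent",
        "recurrent tumors among GSTM2 homozygotes",
        0,
        int((groups[homo] == "recurrent").sum()),
    )
    gstt4 = panel.copies("GSTT4")
    _check(report, "gstt4_hemizygous", "GSTT4 hemizygous tumors", 9, int((gstt4 == 1).sum()))
    gstt1 = panel.copies("GSTT1")
    recurrent = groups[groups == "recurrent"].index
    _check(
        report,
        "recurrent_gstt1_null",
        "recurrent tumors with zero GSTT1 copies",
        2,
        int((gstt1[recurrent] == 0).sum()),
    )

    # --- GSTM1 vs GSTT1 correlation (GAPDH-relative x1000 values) ---
    corr = pearson_with_ci(gstm1_expr.to_numpy(), panel.expression("GSTT1").to_numpy())
    _check(report, "gstm1_gstt1_r", "Pearson r, GSTM1 vs GSTT1", -0.0232, corr.r, 0.0005)
    _check(report, "gstm1_gstt1_ci_low", "Fisher-z 95% CI lower bound", -0.5130, corr.ci_low, 0.001)
    _check(report, "gstm1_gstt1_ci_high", "Fisher-z 95% CI upper bound", 0.4780, corr.ci_high, 0.001)
    _check(report, "gstm1_gstt1_p", "two-sided p-value", 0.9321, corr.p_value, 0.001)

    # --- cohort summaries ---
    summary = summarize_cohort(cohort)
    _check(report, "median_age_recurrent", "median recurrent age", 58, summary.median_age_recurrent)
    _check(report, "median_rin_raw", "raw median RIN", 9.15, summary.median_rin, 1e-9)
    _check(report, "median_rin_rounded", "median RIN (1 dp)", 9.2, summary.median_rin_rounded, 1e-9)

    # --- genotype calls under the GSTM1/GSTM2 scheme ---
    calls, gsum = genotype_cohort(panel, GSTM1_SCHEME, cohort)
    for variant, expected in zip("ABCDEF", (1, 8, 3, 4, 0, 0)):
        _check(
            report,
            f"variant_count_{variant}",
            f"tumors classified as variant {variant}",
            expected,
            gsum["variant_counts"][variant],
        )
    _check(
        report,
        "recurrent_null_genotype",
        "recurrent tumors with GSTM1 null genotype",
        4,
        gsum.get("null_by_group", {}).get("recurrent", 0),
    )
    _check(
        report,
        "gstm1_expr_copy_discordance",
        "tumors with GSTM1 expression/copy discordance",
        0,
        gsum["n_discordant"],
    )

    # --- GSTM2 dosage effect ---
    _, ratios = dosage_analysis(
        panel.expression("GSTM2").to_numpy(), panel.copies("GSTM2").to_numpy()
    )
    _check(report, "gstm2_dosage_ratio", "GSTM2 2-copy/1-copy mean ratio", 1.87, ratios[(1, 2)], 0.05)

    # --- GSTT1 scheme: recurrent copy heterogeneity ---
    _check(
        report,
        "recurrent_gstt1_two_copy",
        "recurrent tumors with two GSTT1 copies",
        1,
        int((gstt1[recurrent] == 2).sum()),
    )
    return report
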