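"""Real-time qPCR quantification.

Standard-curve fitting from plasmid serial dilutions, Ct-to-quantity
conversion, duplex copy-number calling against a 2-copy reference gene
(APOB), and comparative delta-Ct relative quantification against an
internal control (GAPDH).

Copy numbers per cell (diploid genome) follow the duplex TaqMan design:
the target and the reference are amplified in the same reaction, each Ct
is converted to an absolute quantity through its gene's plasmid standard
curve, and the copy number is ``2 * target_quantity / APOB_quantity``.
Relative mRNA quantity is the comparative method without a calibrator
sample: ``RQ = 2**(-(Ct_target - Ct_GAPDH))``, reported on the x1000 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurve",
    "QpcrMeasurement",
    "CopyNumberCall",
    "RelativeQuantity",
    "CurveFitError",
    "QpcrError",
    "fit_standard_curve",
    "quantity_from_ct",
    "estimate_copy_number",
    "compute_rq",
    "check_linear_range",
    "read_plate",
    "read_dilution_series",
    "MAX_INPUT_RNA_NG",
    "COPY_CALL_TOLERANCE",
]

#: Input RNA must stay strictly below this mass per reaction for the
#: GAPDH signal to remain in the linear range.
MAX_INPUT_RNA_NG = 200.0

#: Continuous copy estimates farther than this from the nearest integer
#: are still called but flagged low-confidence.
COPY_CALL_TOLERANCE = 0.3


class CurveFitError(ValueError):
    """Standard-curve fitting failed or produced an invalid curve."""


class QpcrError(ValueError):
    """A quantification contract was violated (missing reference, mismatched
    samples, out-of-domain Ct...)."""


@dataclass(frozen=True)
class DilutionSeries:
    """Plasmid serial-dilution points: known copies/reaction with Ct replicates."""

    quantities: tuple[float, ...]
    ct_replicates: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.quantities) != len(self.ct_replicates):
            raise ValueError("quantities and ct_replicates must align")
        if any(q <= 0 for q in self.quantities):
            raise ValueError("dilution quantities must be positive")
        if any(len(r) == 0 for r in self.ct_replicates):
            raise ValueError("every dilution point needs at least one Ct replicate")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear relation Ct = intercept + slope * log10(quantity).

    ``efficiency`` is the per-cycle amplification gain as a fraction
    (1.0 = perfect doubling, corresponding to slope -3.3219).
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    linear_range: tuple[float, float]

    @property
    def valid(self) -> bool:
        return self.slope < 0


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for one assay on one sample.

    ``undetected_flag`` marks no-amplification wells explicitly; sentinel
    Ct values (e.g. 40) are never used for absence.
    """

    sample_id: str
    assay: str
    ct_replicates: tuple[float, ...] = ()
    reporter: str = "FAM"
    undetected_flag: bool = False

    def __post_init__(self) -> None:
        if self.undetected_flag:
            return
        if len(self.ct_replicates) == 0:
            raise QpcrError(f"{self.sample_id}/{self.assay}: no Ct replicates")
        if any(not (0 < ct < 45) for ct in self.ct_replicates):
            raise QpcrError(f"{self.sample_id}/{self.assay}: Ct outside (0, 45)")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    gene: str
    continuous_estimate: float
    integer_call: int
    within_tolerance: bool
    replicate_cv: float


@dataclass(frozen=True)
class RelativeQuantity:
    sample_id: str
    gene: str
    rq: float
    rq_x1000: float
    delta_ct: float | None
    undetected: bool = False
    qc_flags: tuple[str, ...] = ()


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """Ordinary least squares of mean Ct on log10(known quantity).

    Requires at least two distinct quantities; a non-negative slope (no
    dilution-dependent signal) raises :class:`CurveFitError` rather than
    returning a silently unusable curve.
    """
    qs = np.asarray(series.quantities, dtype=float)
    if len(np.unique(qs)) < 2:
        raise CurveFitError("need at least 2 distinct dilution quantities")
    mean_cts = np.array([np.mean(r) for r in series.ct_replicates])
    res = stats.linregress(np.log10(qs), mean_cts)
    if res.slope >= 0:
        raise CurveFitError(f"non-negative slope {res.slope:.3f}: invalid curve")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency),
        linear_range=(float(qs.min()), float(qs.max())),
    )


def quantity_from_ct(
    ct: float, curve: StandardCurve, *, warn_extrapolation: bool = False
) -> float:
    """Invert the standard curve: copies/reaction for an observed Ct."""
    if not curve.valid:
        raise CurveFitError("cannot invert an invalid (non-negative slope) curve")
    q = 10.0 ** ((ct - curve.intercept) / curve.slope)
    if warn_extrapolation and not (
        curve.linear_range[0] <= q <= curve.linear_range[1]
    ):
        import warnings

        warnings.warn(
            f"quantity {q:.3g} outside fitted linear range {curve.linear_range}",
            stacklevel=2,
        )
    return float(q)


def _replicate_quantities(meas: QpcrMeasurement, curve: StandardCurve) -> np.ndarray:
    return np.array([quantity_from_ct(ct, curve) for ct in meas.ct_replicates])


def estimate_copy_number(
    target: QpcrMeasurement,
    reference: QpcrMeasurement,
    target_curve: StandardCurve,
    reference_curve: StandardCurve,
    *,
    tolerance: float = COPY_CALL_TOLERANCE,
) -> CopyNumberCall:
    """Duplex copy-number call: 2 x (target quantity / reference quantity).

    Quantities (not Ct values) are averaged across replicates. An
    undetected target yields estimate 0 / call 0; an undetected reference
    is an error since the denominator vanishes.
    """
    if target.sample_id != reference.sample_id:
        raise QpcrError(
            f"sample mismatch: target {target.sample_id!r} vs "
            f"reference {reference.sample_id!r}"
        )
    if reference.undetected_flag:
        raise QpcrError(f"{reference.sample_id}: reference assay undetected")
    ref_q = _replicate_quantities(reference, reference_curve)
    if np.mean(ref_q) <= 0:
        raise QpcrError(f"{reference.sample_id}: zero reference quantity")

    if target.undetected_flag:
        return CopyNumberCall(target.sample_id, target.assay, 0.0, 0, True, 0.0)

    tgt_q = _replicate_quantities(target, target_curve)
    estimate = 2.0 * float(np.mean(tgt_q)) / float(np.mean(ref_q))
    call = int(round(estimate))
    cv = float(np.std(tgt_q, ddof=1) / np.mean(tgt_q)) if len(tgt_q) > 1 else 0.0
    return CopyNumberCall(
        sample_id=target.sample_id,
        gene=target.assay,
        continuous_estimate=estimate,
        integer_call=call,
        within_tolerance=abs(estimate - call) <= tolerance,
        replicate_cv=cv,
    )


def compute_rq(
    target: QpcrMeasurement,
    gapdh: QpcrMeasurement,
    *,
    qc_flags: Sequence[str] = (),
) -> RelativeQuantity:
    """Comparative delta-Ct relative quantity against the internal control.

    delta_ct = mean(target Ct) - mean(control Ct); RQ = 2**(-delta_ct).
    Ct values (not quantities) are averaged, mirroring instrument-software
    convention. Undetected target transcripts give RQ 0 with a flag.
    """
    if target.sample_id != gapdh.sample_id:
        raise QpcrError(
            f"sample mismatch: {target.sample_id!r} vs {gapdh.sample_id!r}"
        )
    if gapdh.undetected_flag:
        raise QpcrError(f"{gapdh.sample_id}: internal control undetected")
    if target.undetected_flag:
        return RelativeQuantity(
            target.sample_id, target.assay, 0.0, 0.0, None, True, tuple(qc_flags)
        )
    delta_ct = target.mean_ct - gapdh.mean_ct
    rq = 2.0 ** (-delta_ct)
    return RelativeQuantity(
        sample_id=target.sample_id,
        gene=target.assay,
        rq=rq,
        rq_x1000=1000.0 * rq,
        delta_ct=delta_ct,
        qc_flags=tuple(qc_flags),
    )


def check_linear_range(input_rna_ng: float) -> bool:
    """True iff RNA input is strictly below the 200 ng linear-range bound."""
    if input_rna_ng < 0:
        raise ValueError(f"negative RNA input: {input_rna_ng}")
    return input_rna_ng < MAX_INPUT_RNA_NG


# ---------------------------------------------------------------------------
# plate / dilution table IO
# ---------------------------------------------------------------------------


def read_plate(source: Union[str, Path, IO[str]]) -> list[QpcrMeasurement]:
    """Read a plate table (well, sample_id, assay, reporter, ct).

    One row per replicate; an empty ct field means the well did not
    amplify. Rows are grouped into one measurement per (sample, assay).
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = {"sample_id", "assay", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"plate table missing column(s): {sorted(missing)}")
    out: list[QpcrMeasurement] = []
    for (sample, assay), grp in df.groupby(["sample_id", "assay"], sort=False):
        cts = [float(v) for v in grp["ct"] if str(v).strip() != ""]
        reporter = grp["reporter"].iloc[0] if "reporter" in grp.columns else "FAM"
        if cts:
            out.append(QpcrMeasurement(sample, assay, tuple(cts), reporter))
        else:
            out.append(QpcrMeasurement(sample, assay, (), reporter, undetected_flag=True))
    return out


def read_dilution_series(source: Union[str, Path, IO[str]]) -> DilutionSeries:
    """Read a dilution table (known_quantity, ct); replicate rows share a quantity."""
    df = pd.read_csv(source, sep=None, engine="python")
    if not {"known_quantity", "ct"} <= set(df.columns):
        raise QpcrError("dilution table needs columns known_quantity, ct")
    qs, reps = [], []
    for q, grp in df.groupby("known_quantity", sort=True):
        qs.append(float(q))
        reps.append(tuple(float(v) for v in grp["ct"]))
    return DilutionSeries(tuple(qs), tuple(reps))


def calls_to_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def rqs_to_frame(rqs: Sequence[RelativeQuantity]) -> pd.DataFrame:
    rows = []
    for r in rqs:
        d = dict(r.__dict__)
        d["qc_flags"] = ";".join(d["qc_flags"])
        rows.append(d)
    return pd.DataFrame(rows)
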