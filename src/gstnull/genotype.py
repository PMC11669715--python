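"""Germline-vs-somatic deletion inference at a polymorphic GST locus.

The trick: a gene with a common inherited deletion polymorphism (GSTM1 at
1p13.3, GSTT1 at 22q11.23) is paired with a close neighbor that has no
known deletion polymorphism (GSTM2, GSTT4 respectively). Since every
germline haplotype carries the neighbor, the neighbor's tumor copy number
counts surviving haplotypes and therefore reports somatic arm loss; the
polymorphic gene's copies on those surviving haplotypes can then be
attributed to germline versus somatic origin.

On the (polymorphic_copies, neighbor_copies) grid in {0,1,2}^2 this gives
six deletion histories:

=======  ========  ========  ==============================================
variant  polymorphic neighbor  interpretation
=======  ========  ========  ==============================================
A        0         2         two inherited null alleles, no somatic loss
B        0         1         somatic loss; surviving haplotype is null
                             (modal reading: one inherited null + one
                             somatic loss)
C        1         2         one inherited null, no somatic loss
D        1         1         somatic loss; germline 1 or 2 (ambiguous)
E        2         2         two wild-type alleles
F        0         0         both haplotypes lost somatically
=======  ========  ========  ==============================================

The remaining cells (2,1), (2,0), (1,0) are physically impossible —
present copies exceed surviving haplotypes — and are reported as
INCONSISTENT (assay noise or reference-gene polymorphism) rather than
raised as errors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import pandas as pd

from .cohort import CohortTable, GstPanelTable

__all__ = [
    "PairedLocusScheme",
    "PairedLocusObservation",
    "GenotypeCall",
    "GSTM1_SCHEME",
    "GSTT1_SCHEME",
    "EXPRESSION_ZERO_TOL",
    "classify_variant",
    "call_null_genotype",
    "reconcile_with_cytogenetics",
    "genotype_cohort",
    "calls_to_frame",
]

#: Relative expression (x1000 scale) at or below which a gene counts as
#: unexpressed when checking copy/expression concordance. Separates true
#: zeros from the smallest real signal in the cohort with margin.
EXPRESSION_ZERO_TOL = 0.5

Variant = Literal["A", "B", "C", "D", "E", "F", "INCONSISTENT"]


@dataclass(frozen=True)
class PairedLocusScheme:
    """A polymorphic gene paired with a non-polymorphic same-arm neighbor."""

    polymorphic_gene: str
    neighbor_gene: str
    locus_band: str
    arm: str


GSTM1_SCHEME = PairedLocusScheme("GSTM1", "GSTM2", "1p13.3", "1p")
GSTT1_SCHEME = PairedLocusScheme("GSTT1", "GSTT4", "22q11.23", "22q")


@dataclass(frozen=True)
class PairedLocusObservation:
    sample_id: str
    polymorphic_copies: int
    neighbor_copies: int
    polymorphic_expression_x1000: float | None = None
    cytoband_covers_locus: bool | Literal["unknown"] | None = None


@dataclass(frozen=True)
class GenotypeCall:
    """Deletion-history call for one tumor at one paired locus."""

    sample_id: str
    variant: Variant
    germline_polymorphic_copies: tuple[int, ...]
    somatic_locus_loss: bool
    null_genotype: bool
    ambiguous: bool = False
    discordance_flags: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


# total map on the 3x3 observable grid:
# (polymorphic_copies, neighbor_copies) -> (variant, germline copies, n somatic losses)
_VARIANT_GRID: Mapping[tuple[int, int], tuple[Variant, tuple[int, ...], int]] = {
    (0, 2): ("A", (0,), 0),
    # B's modal reading is one inherited null + one somatic loss (germline 1);
    # an inherited double-null losing one null haplotype is observationally
    # identical, so the compatible germline set is {0, 1}.
    (0, 1): ("B", (0, 1), 1),
    (1, 2): ("C", (1,), 0),
    (1, 1): ("D", (1, 2), 1),  # lost haplotype may have carried either allele
    (2, 2): ("E", (2,), 0),
    (0, 0): ("F", (0, 1, 2), 2),
    (2, 1): ("INCONSISTENT", (), 0),
    (2, 0): ("INCONSISTENT", (), 0),
    (1, 0): ("INCONSISTENT", (), 0),
}


def classify_variant(obs: PairedLocusObservation) -> GenotypeCall:
    """Classify a tumor's deletion history from its observed copy pair.

    Total and deterministic on {0,1,2}^2; copies outside that domain raise
    ``ValueError``. Variant D is flagged ambiguous (germline may have had
    one or two present alleles); variant F leaves the germline fully
    unconstrained for the polymorphic gene.
    """
    p, nb = obs.polymorphic_copies, obs.neighbor_copies
    if p not in (0, 1, 2) or nb not in (0, 1, 2):
        raise ValueError(f"copy numbers must be in {{0,1,2}}, got ({p}, {nb})")
    variant, germline, n_losses = _VARIANT_GRID[(p, nb)]
    return GenotypeCall(
        sample_id=obs.sample_id,
        variant=variant,
        germline_polymorphic_copies=germline,
        somatic_locus_loss=n_losses > 0,
        null_genotype=(p == 0) and variant != "INCONSISTENT",
        ambiguous=len(germline) > 1,
    )


def call_null_genotype(
    copy: int,
    expression_x1000: float,
    expression_zero_tol: float = EXPRESSION_ZERO_TOL,
) -> dict:
    """Null-genotype flag plus copy/expression concordance.

    A null genotype is zero gene copies; the call is concordant when the
    expression evidence agrees (null <-> expression at/below the zero
    tolerance).
    """
    if copy < 0:
        raise ValueError("copy number must be >= 0")
    if expression_x1000 < 0:
        raise ValueError("expression must be >= 0")
    null = copy == 0
    expressed = expression_x1000 > expression_zero_tol
    return {"null": null, "concordant": null != expressed}


def reconcile_with_cytogenetics(
    call: GenotypeCall, covers: bool | Literal["unknown"] | None
) -> GenotypeCall:
    """Cross-check the copy-number-based call against the reported
    cytogenetic loss interval.

    The qPCR copy numbers drive the call; the cytoband descriptor is
    advisory. A disagreement (somatic loss inferred but the reported
    interval does not cover the locus, or vice versa) appends a discordance
    flag without changing the call. Unknown coverage adds a provenance note.
    """
    if covers is None or covers == "unknown":
        return replace(call, notes=call.notes + ("cytoband coverage unknown",))
    if call.variant == "INCONSISTENT":
        return call
    if call.somatic_locus_loss != covers:
        direction = (
            "somatic loss inferred from neighbor copies but reported interval "
            "does not cover the locus"
            if call.somatic_locus_loss
            else "reported interval covers the locus but neighbor copies show "
            "no somatic loss"
        )
        return replace(
            call, discordance_flags=call.discordance_flags + (f"cytogenetics: {direction}",)
        )
    return call


def genotype_cohort(
    panel: GstPanelTable,
    scheme: PairedLocusScheme,
    cohort: CohortTable | None = None,
    *,
    expression_zero_tol: float = EXPRESSION_ZERO_TOL,
) -> tuple[list[GenotypeCall], dict]:
    """Genotype every tumor in a panel under a paired-locus scheme.

    Returns per-tumor calls plus a summary dict with variant counts,
    null-genotype counts (split by clinical group when a cohort table is
    supplied), and the count of INCONSISTENT cells excluded from variant
    totals.
    """
    for gene in (scheme.polymorphic_gene, scheme.neighbor_gene):
        if f"{gene}_copy" not in panel.data.columns:
            from .cohort import SchemaError

            raise SchemaError(f"panel lacks copy column for {gene}")
    copies_p = panel.copies(scheme.polymorphic_gene)
    copies_n = panel.copies(scheme.neighbor_gene)
    expr_p = panel.expression(scheme.polymorphic_gene)

    calls: list[GenotypeCall] = []
    for sample_id in panel.data["sample_id"]:
        obs = PairedLocusObservation(
            sample_id=sample_id,
            polymorphic_copies=int(copies_p[sample_id]),
            neighbor_copies=int(copies_n[sample_id]),
            polymorphic_expression_x1000=float(expr_p[sample_id]),
        )
        call = classify_variant(obs)
        conc = call_null_genotype(
            obs.polymorphic_copies,
            obs.polymorphic_expression_x1000,
            expression_zero_tol,
        )
        if not conc["concordant"]:
            call = replace(
                call,
                discordance_flags=call.discordance_flags
                + ("expression/copy discordance",),
            )
        calls.append(call)

    variant_counts = Counter(c.variant for c in calls if c.variant != "INCONSISTENT")
    summary = {
        "scheme": f"{scheme.polymorphic_gene}/{scheme.neighbor_gene}",
        "variant_counts": {v: variant_counts.get(v, 0) for v in "ABCDEF"},
        "n_inconsistent": sum(c.variant == "INCONSISTENT" for c in calls),
        "n_null_genotype": sum(c.null_genotype for c in calls),
        "n_discordant": sum(bool(c.discordance_flags) for c in calls),
    }
    if cohort is not None:
        groups = cohort.data.set_index("sample_id")["group"]
        by_group: dict[str, int] = {}
        for c in calls:
            if c.null_genotype:
                g = str(groups.get(c.sample_id, "unknown"))
                by_group[g] = by_group.get(g, 0) + 1
        summary["null_by_group"] = by_group
    return calls, summary


def calls_to_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        d = dict(c.__dict__)
        d["germline_polymorphic_copies"] = "/".join(
            map(str, d["germline_polymorphic_copies"])
        )
        d["discordance_flags"] = ";".join(d["discordance_flags"])
        d["notes"] = ";".join(d["notes"])
        rows.append(d)
    return pd.DataFrame(rows)
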