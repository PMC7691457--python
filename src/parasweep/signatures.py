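"""Classification of selection signatures by interval algebra.

Six candidate-region tracks feed the classifier: windowed Fst for the
three population pairs and windowed |iHS| for the three populations.
With two domestic breeds (D1, D2) and a wild reference (R):

* artificial selection in D1:  (FST_D1_R  ∪ IHS_D1) − IHS_R
* parallel selection (PS):     ((FST_D1_R ∩ FST_D2_R) ∪ ((IHS_D1 ∩ IHS_D2) − IHS_R)) − FST_D1_D2
* D1-specific (D1.sp):         ((FST_D1_R ∩ FST_D1_D2) ∪ ((IHS_D1 − IHS_D2) − IHS_R)) − FST_D2_R

Chains evaluate left to right; the trailing Fst subtraction applies to
the whole union.  Subtraction is coordinate-level (bedtools semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .regions import RegionSet


def fst_label(pop_a: str, pop_b: str) -> str:
    return f"FST_{pop_a}_{pop_b}"


def ihs_label(pop: str) -> str:
    return f"IHS_{pop}"


def required_labels(domestic: Sequence[str], reference: str) -> List[str]:
    d1, d2 = domestic
    return [
        fst_label(d1, reference),
        fst_label(d2, reference),
        fst_label(d1, d2),
        ihs_label(d1),
        ihs_label(d2),
        ihs_label(reference),
    ]


@dataclass
class SignatureResult:
    """Classified regions plus per-region operand provenance."""

    artificial: Dict[str, RegionSet]
    parallel: RegionSet
    specific: Dict[str, RegionSet]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def _get(bundle: Dict[str, RegionSet], label: str) -> RegionSet:
    if label not in bundle:
        raise KeyError(f"track bundle missing required track {label!r}")
    return bundle[label]


def classify_artificial(
    bundle: Dict[str, RegionSet],
    domestic: Sequence[str] = ("DLW", "DU"),
    reference: str = "EWB",
) -> Dict[str, RegionSet]:
    """(FST_pop_vs_ref ∪ IHS_pop) − IHS_ref for each domestic breed."""
    ihs_ref = _get(bundle, ihs_label(reference))
    out = {}
    for pop in domestic:
        out[pop] = (
            _get(bundle, fst_label(pop, reference))
            .union(_get(bundle, ihs_label(pop)))
            .subtract(ihs_ref)
        )
    return out


def classify_parallel(
    bundle: Dict[str, RegionSet],
    domestic: Sequence[str] = ("DLW", "DU"),
    reference: str = "EWB",
) -> RegionSet:
    """Regions swept in both domestic breeds, not differentiated between them."""
    d1, d2 = domestic
    fst_branch = _get(bundle, fst_label(d1, reference)).intersect(
        _get(bundle, fst_label(d2, reference))
    )
    ihs_branch = (
        _get(bundle, ihs_label(d1))
        .intersect(_get(bundle, ihs_label(d2)))
        .subtract(_get(bundle, ihs_label(reference)))
    )
    ps = fst_branch.union(ihs_branch).subtract(_get(bundle, fst_label(d1, d2)))
    assert ps.intersect(_get(bundle, fst_label(d1, d2))).is_empty()
    return ps


def classify_specific(
    bundle: Dict[str, RegionSet],
    domestic: Sequence[str] = ("DLW", "DU"),
    reference: str = "EWB",
) -> Dict[str, RegionSet]:
    """Breed-specific sweeps: signature in one breed, differentiated from
    the other, and absent from the other breed's own contrast."""
    d1, d2 = domestic
    out = {}
    for this, other in ((d1, d2), (d2, d1)):
        fst_branch = _get(bundle, fst_label(this, reference)).intersect(
            _get(bundle, fst_label(d1, d2))
        )
        ihs_branch = (
            _get(bundle, ihs_label(this))
            .subtract(_get(bundle, ihs_label(other)))
            .subtract(_get(bundle, ihs_label(reference)))
        )
        sp = fst_branch.union(ihs_branch).subtract(_get(bundle, fst_label(other, reference)))
        assert sp.intersect(_get(bundle, fst_label(other, reference))).is_empty()
        out[this] = sp
    return out


def _provenance(
    results: Dict[str, RegionSet], bundle: Dict[str, RegionSet]
) -> pd.DataFrame:
    rows = []
    for category, regions in results.items():
        for chrom, s, e in regions:
            operands = [
                label
                for label, track in sorted(bundle.items())
                if track.overlaps(chrom, s, e)
            ]
            rows.append((category, chrom, s, e, ",".join(operands)))
    return pd.DataFrame(rows, columns=["category", "chrom", "start", "end", "operands"])


def classify_all(
    bundle: Dict[str, RegionSet],
    domestic: Sequence[str] = ("DLW", "DU"),
    reference: str = "EWB",
) -> SignatureResult:
    """Run all three classifications and attach operand provenance."""
    for label in required_labels(domestic, reference):
        _get(bundle, label)
    artificial = classify_artificial(bundle, domestic, reference)
    parallel = classify_parallel(bundle, domestic, reference)
    specific = classify_specific(bundle, domestic, reference)
    flat = {"PS": parallel}
    flat.update({f"{p}.sp": r for p, r in specific.items()})
    flat.update({f"artificial_{p}": r for p, r in artificial.items()})
    return SignatureResult(
        artificial=artificial,
        parallel=parallel,
        specific=specific,
        provenance=_provenance(flat, bundle),
    )
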