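"""Annotation of called delta-mass peaks against modification databases.

Two-stage matching:

1. Each peak center is matched directly against a curated database of
   previously described variants for the target residue; the closest
   entry wins when its absolute mass error is strictly below the
   tolerance (default 10 mDa).
2. Unmatched centers are explained as cascades: the residual
   (center - base delta) for every base entry is matched against a
   larger Unimod-like table of secondary modifications. Candidates are
   ranked by absolute combined error, then plausibility, then fewest
   implied reaction steps.

Class labels travel with the database rows; the final class of a peak is
the label of its matched entry (cascades inherit the base entry's label),
or "Unknown" when no plausible candidate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import chem
from .discovery import DeltaMassCluster
from .io import CLASS_LABELS, ModificationEntry

__all__ = [
    "CascadeCandidate",
    "AnnotationResult",
    "match_known",
    "enumerate_residuals",
    "match_cascades",
    "annotate_peaks",
    "classify_peaks",
    "summarize_classes",
    "annotation_frame",
]

DEFAULT_TOLERANCE = 0.010  # Da, strict inequality


@dataclass(frozen=True)
class CascadeCandidate:
    """One (base, secondary) explanation of an unmatched center."""

    base: ModificationEntry
    secondary: ModificationEntry
    combined_composition: chem.ElementalComposition
    combined_error: float

    @property
    def plausible(self) -> bool:
        return self.base.plausible and self.secondary.plausible

    @property
    def steps(self) -> int:
        # precomposed combination entries encode extra steps with "+"
        return 2 + self.secondary.name.count("+")


@dataclass
class AnnotationResult:
    """Annotation outcome for one cluster."""

    cluster: DeltaMassCluster
    matched_single: tuple[ModificationEntry, float] | None = None
    candidate_pairs: list[CascadeCandidate] = field(default_factory=list)
    final_class: str = "Unknown"
    final_name: str = "Unknown"

    @property
    def annotation_composition(self) -> chem.ElementalComposition | None:
        if self.matched_single is not None:
            return self.matched_single[0].composition
        if self.candidate_pairs:
            return self.candidate_pairs[0].combined_composition
        return None


def match_known(center: float, db: list[ModificationEntry],
                tol: float = DEFAULT_TOLERANCE
                ) -> tuple[ModificationEntry, float] | None:
    """Best single-entry match within strict tolerance, or None.

    Ties on |error| are broken by plausibility (plausible first), then by
    name order.
    """
    if not db:
        raise ValueError("modification database is empty")
    best = min(db, key=lambda e: (abs(center - e.delta), not e.plausible, e.name))
    error = center - best.delta
    if abs(error) < tol:
        return best, error
    return None


def enumerate_residuals(unknown_centers: list[float],
                        preknown: list[ModificationEntry]
                        ) -> list[tuple[float, ModificationEntry, float]]:
    """Full cross product of unknown centers and base entries.

    Always emits exactly ``len(unknown_centers) * len(preknown)`` records
    of (center, base entry, residual = center - base delta).
    """
    return [(center, base, center - base.delta)
            for center in unknown_centers for base in preknown]


def match_cascades(residuals: list[tuple[float, ModificationEntry, float]],
                   unimod: list[ModificationEntry],
                   tol: float = DEFAULT_TOLERANCE
                   ) -> dict[float, list[CascadeCandidate]]:
    """Match residuals against secondary modifications.

    For each (center, base, residual) record, every secondary entry whose
    delta lies within ``tol`` of the residual yields a candidate. Per
    center, candidates are pooled over bases and sorted by |combined
    error|, then plausibility, then fewest implied steps.
    """
    pooled: dict[float, list[CascadeCandidate]] = {}
    for center, base, residual in residuals:
        pooled.setdefault(center, [])
        for secondary in unimod:
            combined_error = residual - secondary.delta
            if abs(combined_error) < tol:
                pooled[center].append(CascadeCandidate(
                    base=base,
                    secondary=secondary,
                    combined_composition=(base.composition
                                          + secondary.composition),
                    combined_error=combined_error,
                ))
    for center, candidates in pooled.items():
        candidates.sort(key=lambda c: (abs(c.combined_error), not c.plausible,
                                       c.steps, c.base.name, c.secondary.name))
    return pooled


def annotate_peaks(clusters: list[DeltaMassCluster],
                   preknown: list[ModificationEntry],
                   unimod: list[ModificationEntry],
                   tol: float = DEFAULT_TOLERANCE) -> list[AnnotationResult]:
    """Run both matching stages over called peaks and classify them."""
    results = []
    unknown = []
    for cluster in clusters:
        result = AnnotationResult(cluster=cluster)
        result.matched_single = match_known(cluster.center, preknown, tol)
        if result.matched_single is None:
            unknown.append(cluster.center)
        results.append(result)
    if unknown:
        residuals = enumerate_residuals(unknown, preknown)
        cascades = match_cascades(residuals, unimod, tol)
        for result in results:
            if result.matched_single is None:
                result.candidate_pairs = cascades.get(result.cluster.center, [])
    return classify_peaks(results)


def classify_peaks(results: list[AnnotationResult]) -> list[AnnotationResult]:
    """Assign exactly one final class and name per peak.

    A direct match uses the entry's own class; a cascade uses the base
    entry's class (a substitution base keeps the peak in "AA
    substitution", an oxidation base in "Reactive species", ...). Peaks
    whose candidates are all implausible stay "Unknown".
    """
    for result in results:
        if result.matched_single is not None:
            entry, _ = result.matched_single
            result.final_class = entry.class_label
            result.final_name = entry.name
        else:
            chosen = next((c for c in result.candidate_pairs if c.plausible),
                          None)
            if chosen is None:
                result.final_class = "Unknown"
                result.final_name = "Unknown"
            else:
                result.final_class = chosen.base.class_label
                result.final_name = (f"{chosen.base.name} then "
                                     f"{chosen.secondary.name}")
        if result.final_class not in CLASS_LABELS:
            result.final_class = "Unknown"
    return results


def summarize_classes(class_labels, frequencies) -> pd.DataFrame:
    """Per-class frequency totals and percentages of the grand total.

    Accepts parallel sequences of class labels and peak frequencies
    (n_psms). Percentages are rounded half-even to 2 decimals; the class
    totals partition the grand total exactly.
    """
    frame = pd.DataFrame({
        "class": list(class_labels),
        "frequency": list(frequencies),
    })
    if frame.empty:
        return pd.DataFrame(columns=["class", "total_frequency", "percent"])
    totals = frame.groupby("class", sort=False)["frequency"].sum()
    order = [c for c in CLASS_LABELS if c in totals.index]
    order += [c for c in totals.index if c not in order]
    totals = totals.loc[order]
    grand = int(totals.sum())
    summary = pd.DataFrame({
        "class": totals.index,
        "total_frequency": totals.to_numpy(),
        "percent": [round(100.0 * t / grand, 2) for t in totals],
    }).reset_index(drop=True)
    return summary


def summarize_results(results: list[AnnotationResult]) -> pd.DataFrame:
    """Class summary straight from annotation results."""
    return summarize_classes(
        [r.final_class for r in results],
        [r.cluster.n_psms for r in results])


def annotation_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    """Published-summary-style table: one row per peak."""
    rows = []
    for result in results:
        comp = result.annotation_composition
        mono = chem.monoisotopic_mass(comp) if comp is not None else None
        rows.append({
            "classification": result.final_class,
            "delta_mass": result.cluster.center,
            "frequency": result.cluster.n_psms,
            "annotation": result.final_name,
            "chemical_formula": (chem.format_composition(comp)
                                 if comp is not None else ""),
            "monoisotopic_mass": mono,
            "error": (result.cluster.center - mono
                      if mono is not None else None),
        })
    return pd.DataFrame(rows, columns=[
        "classification", "delta_mass", "frequency", "annotation",
        "chemical_formula", "monoisotopic_mass", "error"])
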