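"""Synthetic PSM tables and clinical tables with planted structure.

The generator emulates what the discovery pipeline consumes: confident
PSMs whose delta masses cluster tightly around true modification masses
(Gaussian mass error), a configurable uniform background over the search
range, paired tumor/NAT samples with per-site enrichment effects, and
score/localization/FDR columns with a controllable pass/fail mix.

Everything is driven by a single integer seed; identical inputs produce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .io import PSM_COLUMNS, STANDARD_AA
from .errors import SpecValidationError

__all__ = [
    "PeakSpec",
    "ScoreModel",
    "CohortSpec",
    "generate_psm_table",
    "generate_survival_table",
]

DEFAULT_DELTA_RANGE = (-150.0, 500.0)

_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVY"))  # no W: inserted explicitly


@dataclass(frozen=True)
class PeakSpec:
    """One planted delta-mass peak.

    ``site_pool`` lists the (protein accession, 1-based site) locations the
    peak's PSMs are spread over, uniformly unless a cohort effect reweights
    tumor/NAT membership.
    """

    true_delta: float
    n_psms: int
    mass_sd: float
    residue: str = "W"
    site_pool: tuple[tuple[str, int], ...] = (("PROT1", 10),)

    def validate(self, delta_range=DEFAULT_DELTA_RANGE) -> None:
        if self.n_psms < 0:
            raise SpecValidationError("n_psms", f"must be >= 0, got {self.n_psms}")
        if not self.mass_sd > 0:
            raise SpecValidationError("mass_sd", f"must be > 0, got {self.mass_sd}")
        if self.residue not in STANDARD_AA:
            raise SpecValidationError("residue", f"invalid residue {self.residue!r}")
        if not delta_range[0] <= self.true_delta <= delta_range[1]:
            raise SpecValidationError(
                "true_delta",
                f"{self.true_delta} outside delta range {delta_range}")
        if not self.site_pool:
            raise SpecValidationError("site_pool", "must be non-empty")
        for protein, site in self.site_pool:
            if site < 1:
                raise SpecValidationError("site_pool", f"site {site} < 1 for {protein}")


@dataclass(frozen=True)
class ScoreModel:
    """Pass/fail mix for the three confidence columns.

    Passing draws sit above (below, for FDR) the conventional thresholds
    Score >= 300, Delta Mod Score >= 10, FDR 2D <= 0.01; failing draws sit
    strictly on the wrong side. Shapes are shifted log-normals — only the
    pass/fail mix matters to a threshold filter.
    """

    pass_fraction_score: float = 1.0
    pass_fraction_delta_mod: float = 1.0
    pass_fraction_fdr: float = 1.0

    def validate(self) -> None:
        for name in ("pass_fraction_score", "pass_fraction_delta_mod",
                     "pass_fraction_fdr"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SpecValidationError(name, f"must be in [0, 1], got {value}")

    def draw(self, rng: np.random.Generator, n: int):
        pass_s = rng.random(n) < self.pass_fraction_score
        pass_d = rng.random(n) < self.pass_fraction_delta_mod
        pass_f = rng.random(n) < self.pass_fraction_fdr
        score = np.where(pass_s, 300.0 + rng.lognormal(4.0, 1.0, n),
                         rng.uniform(0.0, 299.9, n))
        dms = np.where(pass_d, 10.0 + rng.lognormal(2.0, 1.0, n),
                       rng.uniform(0.0, 9.9, n))
        fdr = np.where(pass_f, rng.uniform(0.0, 0.01, n),
                       rng.uniform(0.011, 1.0, n))
        return np.round(score, 2), np.round(dms, 2), fdr


@dataclass(frozen=True)
class CohortSpec:
    """Paired tumor/NAT cohort design for the generator.

    ``effect_map`` maps (protein, site, peak index) to a multiplicative
    tumor enrichment e: a PSM at that site from that peak lands in a tumor
    sample with probability e / (1 + e) instead of 1/2.
    """

    n_pairs: int = 1
    effect_map: dict = dataclass_field(default_factory=dict)
    noise_fraction: float = 0.0
    seed: int = 0
    n_noise: int | None = None
    delta_range: tuple[float, float] = DEFAULT_DELTA_RANGE
    score_model: ScoreModel = ScoreModel()
    mislocalization_rate: float = 0.0
    noise_residue: str = "W"

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise SpecValidationError("n_pairs", f"must be >= 1, got {self.n_pairs}")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise SpecValidationError(
                "noise_fraction", f"must be in [0, 1], got {self.noise_fraction}")
        if not self.delta_range[0] < self.delta_range[1]:
            raise SpecValidationError(
                "delta_range", f"lower must be < upper, got {self.delta_range}")
        if self.n_noise is not None and self.n_noise < 0:
            raise SpecValidationError("n_noise", f"must be >= 0, got {self.n_noise}")
        if not 0.0 <= self.mislocalization_rate <= 1.0:
            raise SpecValidationError(
                "mislocalization_rate",
                f"must be in [0, 1], got {self.mislocalization_rate}")
        self.score_model.validate()


def _noise_count(n_planted: int, cohort: CohortSpec) -> int:
    if cohort.n_noise is not None:
        return cohort.n_noise
    if cohort.noise_fraction >= 1.0:
        raise SpecValidationError(
            "n_noise", "required when noise_fraction = 1 (planted count is 0)")
    f = cohort.noise_fraction
    return int(round(n_planted * f / (1.0 - f)))


def _peptides(rng: np.random.Generator, residues: np.ndarray) -> list[str]:
    """Random 9-mers with the target residue at position 5."""
    flanks = rng.choice(_AA_ALPHABET, size=(len(residues), 8))
    return ["".join(f[:4]) + r + "".join(f[4:]) for f, r in zip(flanks, residues)]


def generate_psm_table(peaks: list[PeakSpec], cohort: CohortSpec) -> pd.DataFrame:
    """Generate a PSM table with planted peaks plus uniform background.

    Planted deltas are drawn Normal(true_delta, mass_sd) and clipped to the
    configured range; background deltas are Uniform over the range. Sample
    ids are ``T01``/``N01`` ... per pair, with group labels tumor/NAT.
    """
    cohort.validate()
    for peak in peaks:
        peak.validate(cohort.delta_range)
    if not peaks and cohort.n_noise is None and cohort.noise_fraction < 1.0:
        raise SpecValidationError("peaks", "empty and no noise configured")

    rng = np.random.default_rng(cohort.seed)
    lo, hi = cohort.delta_range
    pair_ids = np.arange(cohort.n_pairs)

    deltas, residues, proteins, sites, is_tumor, pair_of = [], [], [], [], [], []
    for peak_index, peak in enumerate(peaks):
        n = peak.n_psms
        if n == 0:
            continue
        pool = np.arange(len(peak.site_pool))
        chosen = rng.choice(pool, size=n)
        d = np.clip(rng.normal(peak.true_delta, peak.mass_sd, n), lo, hi)
        pairs = rng.choice(pair_ids, size=n)
        for j in range(n):
            protein, site = peak.site_pool[chosen[j]]
            effect = cohort.effect_map.get((protein, site, peak_index), 1.0)
            tumor = rng.random() < effect / (1.0 + effect)
            deltas.append(d[j])
            residues.append(peak.residue)
            proteins.append(protein)
            sites.append(site)
            is_tumor.append(tumor)
            pair_of.append(pairs[j])

    n_planted = len(deltas)
    n_noise = _noise_count(n_planted, cohort)
    if n_noise:
        deltas.extend(rng.uniform(lo, hi, n_noise))
        residues.extend([cohort.noise_residue] * n_noise)
        noise_proteins = rng.integers(1, 200, n_noise)
        noise_sites = rng.integers(1, 500, n_noise)
        proteins.extend(f"NOISE{p:03d}" for p in noise_proteins)
        sites.extend(int(s) for s in noise_sites)
        is_tumor.extend(rng.random(n_noise) < 0.5)
        pair_of.extend(rng.choice(pair_ids, size=n_noise))

    n = len(deltas)
    residues = np.array(residues, dtype=object)
    if cohort.mislocalization_rate > 0 and n:
        corrupt = rng.random(n) < cohort.mislocalization_rate
        wrong = rng.choice(_AA_ALPHABET, size=n)
        residues = np.where(corrupt, wrong, residues)

    score, dms, fdr = cohort.score_model.draw(rng, n)
    pair_of = np.asarray(pair_of, dtype=int)
    is_tumor = np.asarray(is_tumor, dtype=bool)
    sample_id = np.where(
        is_tumor,
        [f"T{p + 1:02d}" for p in pair_of],
        [f"N{p + 1:02d}" for p in pair_of])

    table = pd.DataFrame({
        "spectrum_id": [f"spec{i:07d}" for i in range(n)],
        "peptide": _peptides(rng, residues),
        "protein": proteins,
        "site": np.asarray(sites, dtype=int) if n else np.array([], dtype=int),
        "residue": residues,
        "delta_mass": np.asarray(deltas, dtype=float),
        "score": score,
        "delta_mod_score": dms,
        "fdr_2d": fdr,
        "sample_id": sample_id,
        "group": np.where(is_tumor, "tumor", "NAT"),
    }, columns=list(PSM_COLUMNS))
    return table


def generate_survival_table(n_patients: int, marker_effect: float, seed: int,
                            baseline_hazard: float = 0.1,
                            censor_hazard: float = 0.05) -> pd.DataFrame:
    """Generate exponential survival data with a marker-scaled hazard.

    The per-patient hazard is ``baseline_hazard * marker_effect ** marker``
    with a standard-normal marker, so ``marker_effect`` is the hazard ratio
    per unit of marker. Censoring is independent exponential.
    """
    if n_patients < 2:
        raise SpecValidationError("n_patients", f"must be >= 2, got {n_patients}")
    if not marker_effect > 0:
        raise SpecValidationError(
            "marker_effect", f"must be > 0, got {marker_effect}")
    rng = np.random.default_rng(seed)
    marker = rng.normal(0.0, 1.0, n_patients)
    hazard = baseline_hazard * np.power(marker_effect, marker)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / censor_hazard, n_patients)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
        "time": time,
        "event": event,
        "marker": marker,
    })
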