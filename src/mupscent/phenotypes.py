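"""Urinary protein mass profiles: prediction from transcripts and analysis
of observed ESI/MS peak lists.

Mature MUP isoforms differ by a handful of residues, so their deconvolved
average masses fall into a small set of classes near 18.7 kDa (the published
set is 18645, 18650, 18665, 18683, 18693, 18708, 18713 and 18724 Da).  A
transcript catalog over the discriminating coding window predicts the
proportional abundance of each mass class; an observed profile is the
intensity share of each class in a deconvolved peak list.  Comparing the two
quantifies how faithfully transcription predicts the excreted phenotype, and
within/between-individual profile correlations quantify individuality.

Masses are *average* (not monoisotopic) masses, matching the ESI/MS
deconvolution regime.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .pd_stats import TestReport, regress
from .read_collapse import ExonCatalog

#: average residue masses in Da (residue = amino acid minus water)
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

#: published central-MUP mass classes (Da)
CENTRAL_MUP_MASSES = (18645, 18650, 18665, 18683, 18693, 18708, 18713, 18724)

DEFAULT_BIN_TOLERANCE = 2.5  # Da; ~2 Da variants are indistinguishable


def average_mass(sequence: str, signal_peptide_length: int = 0) -> float:
    """Average molecular mass (Da) of a protein sequence.

    Optionally strips an N-terminal signal peptide of the given length first
    (the signal peptide is cleaved before excretion in urine).
    """
    seq = sequence.upper()[signal_peptide_length:]
    try:
        residues = sum(AVERAGE_RESIDUE_MASS[a] for a in seq)
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r}") from None
    return residues + WATER_MASS


def residue_mass_shift(variant_label: str) -> float:
    """Mass shift (Da) implied by a residue exchange label like ``"R161L"``:
    mass of the new residue minus mass of the old one."""
    m = re.fullmatch(r"([A-Za-z])(\d+)([A-Za-z])", variant_label.strip())
    if not m:
        raise ValidationError(f"cannot parse variant label {variant_label!r}")
    old, _, new = m.groups()
    try:
        return AVERAGE_RESIDUE_MASS[new.upper()] - AVERAGE_RESIDUE_MASS[old.upper()]
    except KeyError as exc:
        raise ValidationError(f"unknown residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class CorrectionSpec:
    """Move a read fraction from one mass class to a shifted class.

    Used for coding variants outside the sequenced window whose carrier
    fraction is known from the variant profile (e.g. R161L): ``fraction`` of
    the total is subtracted from the class at ``source_mass`` and added at
    ``source_mass + mass_shift``.
    """

    variant_label: str
    source_mass: float
    fraction: float
    mass_shift: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("correction fraction must lie in [0, 1]")

    def shift(self) -> float:
        if self.mass_shift is not None:
            return self.mass_shift
        return residue_mass_shift(self.variant_label)


@dataclass
class MassProfile:
    """Proportional abundance over ordered protein-mass bins."""

    individual_id: str
    bins: np.ndarray
    proportions: np.ndarray
    source: str = "observed_ms"
    sample_id: str | None = None
    collection_day: float | None = None

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.bins.shape != self.proportions.shape:
            raise ValidationError("bins and proportions differ in length")
        if np.any(np.diff(self.bins) <= 0):
            raise ValidationError("bins must be strictly increasing")
        if (self.proportions < -1e-12).any():
            raise ValidationError("negative proportion")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("proportions must sum to 1")
        if self.source not in ("observed_ms", "predicted_rna"):
            raise ValidationError(f"unknown profile source {self.source!r}")

    def proportion_at(self, mass: float, tolerance: float = 1e-6) -> float:
        hits = np.abs(self.bins - mass) <= tolerance
        return float(self.proportions[hits].sum())


def _assign_bin(mass: float, bins: list[float], tolerance: float) -> int | None:
    if not bins:
        return None
    arr = np.asarray(bins)
    k = int(np.argmin(np.abs(arr - mass)))
    return k if abs(arr[k] - mass) <= tolerance else None


def predict_mass_profile(
    region_catalog: ExonCatalog,
    masses: Mapping[str, float],
    individual_id: str,
    bins: Sequence[float] | None = None,
    corrections: Iterable[CorrectionSpec] = (),
    tolerance: float = DEFAULT_BIN_TOLERANCE,
) -> MassProfile:
    """Predict the urinary mass profile from an accepted transcript catalog.

    ``masses`` maps each accepted sequence to the average mass (Da) of the
    mature protein it encodes.  Proportions are pooled into the nearest bin
    within ``tolerance``; a sequence matching no bin opens a new bin with a
    warning.  Corrections then move carrier fractions between classes and the
    result is renormalised.
    """
    if not region_catalog.accepted:
        raise ValidationError("catalog has no accepted sequences")
    bin_list = sorted(float(b) for b in bins) if bins else []
    weights: dict[float, float] = {b: 0.0 for b in bin_list}
    for rec in region_catalog.accepted:
        if rec.sequence not in masses:
            raise ValidationError(
                f"no mass known for accepted sequence {rec.sequence[:20]!r}..."
            )
        m = float(masses[rec.sequence])
        k = _assign_bin(m, bin_list, tolerance)
        if k is None:
            warnings.warn(
                f"mass {m:.1f} Da matches no bin within {tolerance} Da; "
                "creating a new bin",
                stacklevel=2,
            )
            bin_list = sorted(bin_list + [m])
            weights.setdefault(m, 0.0)
            center = m
        else:
            center = bin_list[k]
        weights[center] += rec.proportion

    for corr in corrections:
        k = _assign_bin(corr.source_mass, bin_list, tolerance)
        if k is None:
            raise ValidationError(
                f"correction {corr.variant_label}: source mass "
                f"{corr.source_mass} matches no bin"
            )
        src = bin_list[k]
        moved = min(corr.fraction, weights[src])
        if moved < corr.fraction - 1e-12:
            warnings.warn(
                f"correction {corr.variant_label}: fraction {corr.fraction} "
                f"exceeds bin weight {weights[src]:.4f}; clamped",
                stacklevel=2,
            )
        target_mass = src + corr.shift()
        kt = _assign_bin(target_mass, bin_list, tolerance)
        if kt is None:
            bin_list = sorted(bin_list + [target_mass])
            weights.setdefault(target_mass, 0.0)
            target = target_mass
        else:
            target = bin_list[kt]
        weights[src] -= moved
        weights[target] += moved

    centers = sorted(b for b in bin_list if weights.get(b, 0.0) > 0 or b in bin_list)
    props = np.array([weights[b] for b in centers])
    total = props.sum()
    if total <= 0:
        raise ValidationError("all mass weight removed by corrections")
    return MassProfile(
        individual_id=individual_id,
        bins=np.array(centers),
        proportions=props / total,
        source="predicted_rna",
    )


def proportional_profile(
    peaks: Iterable[tuple[float, float]],
    bins: Sequence[float] = CENTRAL_MUP_MASSES,
    tolerance: float = DEFAULT_BIN_TOLERANCE,
    individual_id: str = "",
    sample_id: str | None = None,
    collection_day: float | None = None,
) -> MassProfile:
    """Observed mass profile from a deconvolved (mass, intensity) peak list.

    Each peak joins the nearest bin within ``tolerance``; duplicate peaks in
    one bin sum.  Peaks matching no bin are dropped before normalisation
    (the unmatched tally is recorded on the returned profile).
    """
    bin_list = sorted(float(b) for b in bins)
    weights = {b: 0.0 for b in bin_list}
    n_unmatched = 0
    n_peaks = 0
    for mass, intensity in peaks:
        n_peaks += 1
        if intensity < 0:
            raise ValidationError("negative peak intensity")
        k = _assign_bin(float(mass), bin_list, tolerance)
        if k is None:
            n_unmatched += 1
        else:
            weights[bin_list[k]] += float(intensity)
    total = sum(weights.values())
    if n_peaks == 0 or total <= 0:
        raise ValidationError("no peak matched any bin")
    keep = [b for b in bin_list if weights[b] > 0]
    profile = MassProfile(
        individual_id=individual_id,
        bins=np.array(keep),
        proportions=np.array([weights[b] / total for b in keep]),
        source="observed_ms",
        sample_id=sample_id,
        collection_day=collection_day,
    )
    profile.n_unmatched = n_unmatched  # tally, not part of the dataclass contract
    return profile


@dataclass(frozen=True)
class IndividualityResult:
    """Within- vs between-individual profile correlations."""

    self_r: np.ndarray
    other_r: np.ndarray
    ks: TestReport
    median_self_r: float
    median_other_r: float
    time_lag_regression: TestReport | None
    n_excluded: int


def _common_proportions(a: MassProfile, b: MassProfile) -> tuple[np.ndarray, np.ndarray]:
    bins = sorted(set(a.bins) | set(b.bins))
    return (
        np.array([a.proportion_at(m) for m in bins]),
        np.array([b.proportion_at(m) for m in bins]),
    )


def individuality_stats(profiles: Sequence[MassProfile]) -> IndividualityResult:
    """Pearson correlations of mass profiles within and between individuals.

    Every same-individual pair of replicate samples contributes to the
    "self" distribution, every cross-individual pair to the "other"
    distribution; the two are compared with a two-sample KS test.  When
    replicate collection days are present, self correlations are regressed
    on the days between samples.  Constant (zero-variance) profiles make r
    undefined; such pairs are excluded with a tally.
    """
    by_ind: dict[str, list[MassProfile]] = {}
    for p in profiles:
        by_ind.setdefault(p.individual_id, []).append(p)
    if not any(len(v) >= 2 for v in by_ind.values()):
        raise ValidationError("need >= 2 replicates for at least one individual")

    self_r, other_r, lags = [], [], []
    n_excluded = 0
    for a, b in itertools.combinations(profiles, 2):
        x, y = _common_proportions(a, b)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_excluded += 1
            continue
        r = float(stats.pearsonr(x, y).statistic)
        if a.individual_id == b.individual_id:
            self_r.append(r)
            if a.collection_day is not None and b.collection_day is not None:
                lags.append(abs(a.collection_day - b.collection_day))
        else:
            other_r.append(r)
    if not self_r or not other_r:
        raise ValidationError("need both self and cross-individual pairs")
    self_r = np.array(self_r)
    other_r = np.array(other_r)
    ks_res = stats.ks_2samp(self_r, other_r)
    ks = TestReport("ks", float(ks_res.statistic), float(ks_res.pvalue),
                    (self_r.size, other_r.size))
    lag_rep = None
    if len(lags) == len(self_r) and len(lags) >= 3 and np.ptp(lags) > 0:
        lag_rep = regress(np.array(lags), self_r)
    return IndividualityResult(
        self_r=self_r,
        other_r=other_r,
        ks=ks,
        median_self_r=float(np.median(self_r)),
        median_other_r=float(np.median(other_r)),
        time_lag_regression=lag_rep,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class PredictedObservedResult:
    pred: np.ndarray
    obs: np.ndarray
    regression: TestReport
    n_individuals: int


def predicted_vs_observed(
    pred: Sequence[MassProfile], obs: Sequence[MassProfile]
) -> PredictedObservedResult:
    """Pooled regression of observed on predicted proportions.

    Pairs every (individual, mass bin) present in both the predicted and the
    observed profile of that individual; one individual may contribute
    several observed replicates.
    """
    pred_by_ind = {p.individual_id: p for p in pred}
    xs, ys = [], []
    n_ind = 0
    seen = set()
    for o in obs:
        p = pred_by_ind.get(o.individual_id)
        if p is None:
            continue
        if o.individual_id not in seen:
            seen.add(o.individual_id)
            n_ind += 1
        bins = sorted(set(p.bins) & set(o.bins))
        for m in bins:
            xs.append(p.proportion_at(m))
            ys.append(o.proportion_at(m))
    if not xs:
        raise ValidationError("no shared individuals/bins between sets")
    x = np.array(xs)
    y = np.array(ys)
    return PredictedObservedResult(
        pred=x, obs=y, regression=regress(x, y), n_individuals=n_ind
    )
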