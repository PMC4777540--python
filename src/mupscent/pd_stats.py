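"""Pairwise difference (PD) statistics over variant profiles.

For two individuals the raw index PD' is the L1 distance between their
profiles expressed as read *fractions*:

    PD'(i, j) = sum over sites |p_i - p_j|,   p = percent / 100

tallied across all variant sites of a class (sites where both are zero
contribute nothing, so including them is harmless).  PD is PD' divided by a
site-count denominator, allowing comparisons between site classes that span
different numbers of sites.  PD ignores linkage among variants by design:
reads from collapsed paralogs cannot be phased.

The module also houses the distribution comparisons used around PD
(Mann-Whitney, Kolmogorov-Smirnov, paired Wilcoxon), the RNA-vs-DNA delta-PD
analysis, ordinary least-squares regression reporting, and a Nei-Gojobori
style site counter for deriving PD denominators from a coding sequence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import MupscentError, ValidationError
from .profiles import VariantProfileMatrix

TESTS = ("mann_whitney", "ks", "paired_wilcoxon")


@dataclass(frozen=True)
class PDResult:
    """Pairwise difference between two individuals over one site class."""

    pair: tuple[str, str]
    pd_raw: float
    site_class: str | None = None
    denominator: int | None = None

    @property
    def pd_per_site(self) -> float | None:
        if self.denominator is None:
            return None
        return self.pd_raw / self.denominator


@dataclass(frozen=True)
class TestReport:
    """A named two-sample (or one-sample) test outcome."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    tail: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _profile_fractions(
    matrix: VariantProfileMatrix, site_class: str | None
) -> VariantProfileMatrix:
    return matrix if site_class is None else matrix.filter_by_class(site_class)


def pd_pair(
    matrix: VariantProfileMatrix,
    i: str,
    j: str,
    site_class: str | None = None,
    denominator: int | None = None,
) -> PDResult:
    """PD' between individuals ``i`` and ``j`` (self-comparison allowed)."""
    sub = _profile_fractions(matrix, site_class)
    pi = sub.column(i) / 100.0
    pj = sub.column(j) / 100.0
    if denominator is not None and denominator < 1:
        raise ValidationError("denominator must be a positive integer")
    return PDResult(
        pair=tuple(sorted((i, j))),
        pd_raw=float(np.abs(pi - pj).sum()),
        site_class=site_class,
        denominator=denominator,
    )


def pd_all_pairs(
    matrix: VariantProfileMatrix,
    site_class: str | None = None,
    denominator: int | None = None,
) -> list[PDResult]:
    """PD' for all C(n, 2) unordered pairs, in lexicographic id order."""
    if matrix.n_individuals < 2:
        raise ValidationError("need at least two individuals")
    ids = sorted(matrix.individuals)
    sub = _profile_fractions(matrix, site_class)
    cols = {k: sub.column(k) / 100.0 for k in ids}
    out = []
    for a, b in itertools.combinations(ids, 2):
        out.append(
            PDResult(
                pair=(a, b),
                pd_raw=float(np.abs(cols[a] - cols[b]).sum()),
                site_class=site_class,
                denominator=denominator,
            )
        )
    return out


def compare_pd_sets(a, b, test: str = "mann_whitney") -> TestReport:
    """Two-sample comparison of PD (or any) value sets.

    Mann-Whitney uses midranks for ties; the exact null distribution is used
    for small tie-free samples (both n <= 20), the tie-corrected normal
    approximation otherwise.  ``ks`` is the two-sample sup-distance test and
    ``paired_wilcoxon`` the signed-rank test on paired values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both value sets must be non-empty")
    extra = {"median_a": float(np.median(a)), "median_b": float(np.median(b))}
    if test == "mann_whitney":
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        extra["method"] = method
        return TestReport("mann_whitney", float(res.statistic), float(res.pvalue),
                          (a.size, b.size), extra=extra)
    if test == "ks":
        res = stats.ks_2samp(a, b)
        return TestReport("ks", float(res.statistic), float(res.pvalue),
                          (a.size, b.size), extra=extra)
    if test == "paired_wilcoxon":
        if a.size != b.size:
            raise ValidationError("paired test needs equal-length sets")
        if np.all(a == b):
            return TestReport("paired_wilcoxon", 0.0, float("nan"),
                              (a.size, b.size), extra={**extra, "degenerate": True})
        res = stats.wilcoxon(a, b)
        return TestReport("paired_wilcoxon", float(res.statistic), float(res.pvalue),
                          (a.size, b.size), extra=extra)
    raise MupscentError(f"unknown test {test!r}; expected one of {TESTS}")


@dataclass(frozen=True)
class DeltaPDResult:
    """RNA-minus-DNA PD' deltas for every pair and per-individual means."""

    pairs: list[tuple[str, str]]
    pair_deltas: np.ndarray
    individuals: list[str]
    individual_mean_deltas: np.ndarray
    t_pairs: TestReport
    t_individuals: TestReport
    n_pairs_positive: int
    n_individuals_positive: int


def _one_sample_t(x: np.ndarray, name: str) -> TestReport:
    if np.allclose(x, x[0]):
        # zero variance: t undefined
        return TestReport(name, float("nan"), float("nan"), (x.size,),
                          extra={"degenerate": True, "mean": float(x.mean())})
    res = stats.ttest_1samp(x, 0.0)
    return TestReport(name, float(res.statistic), float(res.pvalue), (x.size,),
                      extra={"df": x.size - 1, "mean": float(x.mean())})


def delta_pd(
    dna_matrix: VariantProfileMatrix,
    rna_matrix: VariantProfileMatrix,
    site_class: str | None = None,
) -> DeltaPDResult:
    """Does variable transcription make individuals more or less distinct?

    For every unordered pair the delta is RNA PD' minus DNA PD'; positive
    values mean the pair is more different at the transcript level.  Both a
    pooled one-sample t over pairs and a t over the per-individual means of
    each individual's pair deltas are reported (the latter matching an
    n-individuals minus 1 df design).
    """
    if set(dna_matrix.individuals) != set(rna_matrix.individuals):
        raise ValidationError("matrices cover different individuals")
    d_coords = [s.coordinate for s in dna_matrix.sites]
    r_coords = [s.coordinate for s in rna_matrix.sites]
    if d_coords != r_coords:
        raise ValidationError("matrices cover different sites")
    dna = pd_all_pairs(dna_matrix, site_class)
    rna = pd_all_pairs(rna_matrix, site_class)
    pairs = [r.pair for r in dna]
    deltas = np.array([r.pd_raw - d.pd_raw for r, d in zip(rna, dna)])
    ids = sorted(dna_matrix.individuals)
    means = np.array(
        [np.mean([dl for p, dl in zip(pairs, deltas) if ind in p]) for ind in ids]
    )
    return DeltaPDResult(
        pairs=pairs,
        pair_deltas=deltas,
        individuals=ids,
        individual_mean_deltas=means,
        t_pairs=_one_sample_t(deltas, "t_pairs"),
        t_individuals=_one_sample_t(means, "t_individuals"),
        n_pairs_positive=int((deltas > 0).sum()),
        n_individuals_positive=int((means > 0).sum()),
    )


def regress(x, y) -> TestReport:
    """OLS with intercept; the statistic is the slope's t with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length inputs with n >= 3")
    if np.allclose(x, x[0]):
        raise ValidationError("zero variance in x")
    if np.ptp(y) == 0:
        return TestReport(
            "ols_slope_t", 0.0, 1.0, (x.size,),
            extra={"slope": 0.0, "intercept": float(y[0]), "r2": 0.0,
                   "df": x.size - 2},
        )
    res = stats.linregress(x, y)
    if res.stderr == 0:
        t = 0.0 if res.slope == 0 else float("inf")
    else:
        t = res.slope / res.stderr
    return TestReport(
        "ols_slope_t",
        float(t),
        float(res.pvalue),
        (x.size,),
        extra={
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r2": float(res.rvalue**2),
            "df": x.size - 2,
        },
    )


def frequency_spectrum(matrix: VariantProfileMatrix):
    """Per-site (n_carriers, mean_pct_all) records split by site class.

    Returns a dict mapping each site class present in the matrix to a
    DataFrame of its sites' carrier counts and population-mean read
    percentages — the two frequency-spectrum axes compared between classes.
    """
    from .profiles import summaries_frame, summarize_sites

    frame = summaries_frame(summarize_sites(matrix))
    return {
        cls: sub[["site", "n_carriers", "mean_pct_all"]].reset_index(drop=True)
        for cls, sub in frame.groupby("class", dropna=False)
    }


# -- Nei-Gojobori site counts ------------------------------------------------


def ng_site_counts(cds: str) -> tuple[float, float]:
    """Nei-Gojobori (1986) counts of non-synonymous and synonymous sites.

    For every codon position, the synonymous fraction is the share of the
    three possible point changes that leave the amino acid unchanged (changes
    creating a stop count as non-synonymous).  Returns ``(n_nonsyn_sites,
    n_syn_sites)``; they sum to the coding length.  Useful for deriving PD
    per-site denominators from a reference coding sequence.
    """
    from Bio.Seq import Seq

    cds = cds.upper().replace("\n", "").replace(" ", "")
    if len(cds) % 3 != 0:
        raise ValidationError("coding sequence length must be a multiple of 3")
    if set(cds) - set("ACGT"):
        raise ValidationError("coding sequence must be unambiguous A/C/G/T")
    syn = 0.0
    for k in range(0, len(cds), 3):
        codon = cds[k : k + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            raise ValidationError(f"internal stop codon at position {k + 1}")
        for pos in range(3):
            n_syn = 0
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                mut_aa = str(Seq(mut).translate())
                if mut_aa == aa:
                    n_syn += 1
            syn += n_syn / 3.0
    return len(cds) - syn, syn


def ng_site_counts_fasta(path) -> tuple[float, float]:
    """Like :func:`ng_site_counts`, reading the first record of a FASTA file."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return ng_site_counts(str(record.seq))
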