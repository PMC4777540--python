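"""Collapsed-paralog variant profiles.

Reads from a family of near-identical tandem paralogs are aligned to a single
representative gene, so each site is summarised as the *percentage of reads
carrying the non-reference base* in each individual.  A value mixes allelic
and paralogous variation deliberately: from the point of view of the scent
phenotype it does not matter whether a novel isoform is an allele or a
paralog.  The central container here, :class:`VariantProfileMatrix`, is a
sites x individuals table of such percentages plus a mask for low-coverage
cells.

Two transcriptions of published variant tables (11 non-synonymous and 22
synonymous sites across 18 wild-derived mice) ship with the package and are
available through :func:`load_nonsynonymous_table`, :func:`load_synonymous_table` and
:func:`load_combined_tables`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    UnknownBaseError,
    UnknownIndividualError,
    UnknownSiteClassError,
    ValidationError,
)

NUCLEOTIDES = ("A", "C", "G", "T")

#: recognised site categories
SITE_CLASSES = ("nonsynonymous", "synonymous", "intron", "promoter")

DEFAULT_MIN_READS = 100


@dataclass(frozen=True)
class SiteRecord:
    """A single variant site on the reference paralog.

    ``coordinate`` is an opaque genomic label (e.g. ``"chr4:60661740"``); no
    liftover or strand logic is applied.  ``aa_change`` is only meaningful for
    non-synonymous sites; ``novel`` marks variants absent from the reference
    genome.
    """

    coordinate: str
    site_class: str | None = None
    aa_change: str | None = None
    novel: bool | None = None

    def __post_init__(self) -> None:
        if self.site_class is not None and self.site_class not in SITE_CLASSES:
            raise UnknownSiteClassError(
                f"unknown site class {self.site_class!r}; "
                f"expected one of {SITE_CLASSES}"
            )
        if self.aa_change is not None and self.site_class not in (
            None,
            "nonsynonymous",
        ):
            raise ValidationError(
                "aa_change is only meaningful for nonsynonymous sites, "
                f"got {self.aa_change!r} on a {self.site_class} site"
            )


@dataclass(frozen=True)
class SiteSummary:
    """Frequency-spectrum summary of one site across individuals.

    ``mean_pct_all`` sums the percentage of non-reference reads over *all*
    individuals and divides by the number of individuals (carriers or not);
    ``mean_pct_carriers`` averages over carriers only and is NaN when the
    site has no carriers.
    """

    site: SiteRecord
    n_carriers: int
    mean_pct_all: float
    mean_pct_carriers: float


class BaseCountTable:
    """Per-site read counts of the four nucleotides for one individual.

    Wraps a DataFrame with columns ``site, ref, A, C, G, T``; one row per
    site on the reference paralog.
    """

    def __init__(self, individual_id: str, frame: pd.DataFrame):
        required = {"site", "ref", *NUCLEOTIDES}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"base-count table missing columns {sorted(missing)}")
        refs = frame["ref"].astype(str).str.upper()
        bad = ~refs.isin(NUCLEOTIDES)
        if bad.any():
            raise UnknownBaseError(
                f"unknown reference base(s) {sorted(refs[bad].unique())}"
            )
        counts = frame[list(NUCLEOTIDES)].to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise ValidationError("base counts must be numeric")
        if (counts < 0).any():
            raise ValidationError("negative base count")
        if frame["site"].duplicated().any():
            raise ValidationError("duplicate site rows in base-count table")
        self.individual_id = individual_id
        self.frame = frame.assign(ref=refs).reset_index(drop=True)

    @classmethod
    def read(cls, path, individual_id: str | None = None) -> "BaseCountTable":
        """Read a tab-delimited counts file (``site  ref  A  C  G  T``)."""
        frame = pd.read_csv(path, sep="\t")
        frame.columns = [c.strip() for c in frame.columns]
        if individual_id is None:
            import os

            individual_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(individual_id, frame)


class VariantProfileMatrix:
    """Sites x individuals matrix of percent non-reference reads.

    ``values`` is float percent on the 0-100 scale, as printed in the source
    tables; conversion to fractions happens only inside the pairwise
    difference computation.  ``masked`` marks low-coverage cells, which carry
    value 0.  Site order is preserved as given (coordinates are opaque
    labels).
    """

    def __init__(
        self,
        individuals: Sequence[str],
        sites: Sequence[SiteRecord],
        values: np.ndarray,
        masked: np.ndarray | None = None,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sites), len(individuals)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(sites)} sites x {len(individuals)} individuals"
            )
        if masked is None:
            masked = np.zeros(values.shape, dtype=bool)
        masked = np.asarray(masked, dtype=bool)
        if masked.shape != values.shape:
            raise ValidationError("mask shape mismatch")
        if np.isnan(values).any():
            raise ValidationError("NaN in profile values")
        if ((values < 0) | (values > 100)).any():
            raise ValidationError("profile values must lie in [0, 100]")
        if (values[masked] != 0).any():
            raise ValidationError("masked cells must carry value 0")
        coords = [s.coordinate for s in sites]
        if len(set(coords)) != len(coords):
            raise ValidationError("duplicate site coordinates")
        if len(set(individuals)) != len(individuals):
            raise ValidationError("duplicate individual ids")
        self.individuals = list(individuals)
        self.sites = list(sites)
        self.values = values
        self.masked = masked

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def column(self, individual_id: str) -> np.ndarray:
        """Percent values for one individual, ordered as ``self.sites``."""
        try:
            j = self.individuals.index(individual_id)
        except ValueError:
            raise UnknownIndividualError(individual_id) from None
        return self.values[:, j]

    # -- construction / IO ----------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VariantProfileMatrix":
        """Build from a wide table: ``site`` column, optional ``class`` /
        ``aa_change`` / ``novel`` columns, one column per individual.  Blank
        cells are read as 0 and unmasked (absence, not missingness)."""
        if "site" not in frame.columns:
            raise ValidationError("profile table needs a 'site' column")
        meta_cols = [c for c in ("site", "class", "aa_change", "novel") if c in frame]
        indiv_cols = [c for c in frame.columns if c not in meta_cols]
        if not indiv_cols:
            raise ValidationError("profile table has no individual columns")
        sites = []
        for _, row in frame.iterrows():
            novel = row.get("novel")
            if pd.isna(novel):
                novel = None
            else:
                novel = bool(int(novel))
            aa = row.get("aa_change")
            cls_ = row.get("class")
            sites.append(
                SiteRecord(
                    coordinate=str(row["site"]),
                    site_class=None if pd.isna(cls_) else str(cls_),
                    aa_change=None if pd.isna(aa) else str(aa),
                    novel=novel,
                )
            )
        values = frame[indiv_cols].fillna(0.0).to_numpy(dtype=float)
        return cls(indiv_cols, sites, values)

    @classmethod
    def read_csv(cls, path) -> "VariantProfileMatrix":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self, blank_zeros: bool = False) -> pd.DataFrame:
        """Wide-table export; with ``blank_zeros`` zero cells become blanks,
        mirroring the printed-table convention."""
        data: dict[str, object] = {"site": [s.coordinate for s in self.sites]}
        if any(s.site_class is not None for s in self.sites):
            data["class"] = [s.site_class for s in self.sites]
        if any(s.aa_change is not None for s in self.sites):
            data["aa_change"] = [s.aa_change for s in self.sites]
        if any(s.novel is not None for s in self.sites):
            data["novel"] = [
                None if s.novel is None else int(s.novel) for s in self.sites
            ]
        for j, ind in enumerate(self.individuals):
            col = self.values[:, j]
            if blank_zeros:
                data[ind] = [v if v != 0 else None for v in col]
            else:
                data[ind] = col
        return pd.DataFrame(data)

    def to_csv(self, path, blank_zeros: bool = False) -> None:
        self.to_frame(blank_zeros=blank_zeros).to_csv(path, index=False)

    # -- operations -------------------------------------------------------

    def filter_by_class(self, class_label: str) -> "VariantProfileMatrix":
        """Retain exactly the sites of one class, preserving order."""
        if class_label not in SITE_CLASSES:
            raise UnknownSiteClassError(class_label)
        keep = [i for i, s in enumerate(self.sites) if s.site_class == class_label]
        return VariantProfileMatrix(
            self.individuals,
            [self.sites[i] for i in keep],
            self.values[keep, :],
            self.masked[keep, :],
        )

    def drop_individual(self, individual_id: str) -> "VariantProfileMatrix":
        """Remove one individual.  Sites left all-zero are retained; use
        :meth:`monomorphic_sites` to inspect them."""
        if individual_id not in self.individuals:
            raise UnknownIndividualError(individual_id)
        keep = [j for j, ind in enumerate(self.individuals) if ind != individual_id]
        out = VariantProfileMatrix(
            [self.individuals[j] for j in keep],
            self.sites,
            self.values[:, keep],
            self.masked[:, keep],
        )
        if out.n_individuals == 0:
            warnings.warn("matrix now has no individuals", stacklevel=2)
        return out

    def monomorphic_sites(self) -> list[SiteRecord]:
        """Sites with no unmasked non-zero value in any individual."""
        if self.n_individuals == 0:
            return list(self.sites)
        allzero = (self.values == 0).all(axis=1)
        return [s for s, z in zip(self.sites, allzero) if z]

    def concat_sites(self, other: "VariantProfileMatrix") -> "VariantProfileMatrix":
        """Stack two matrices over the same individuals (e.g. the
        non-synonymous and synonymous tables)."""
        if other.individuals != self.individuals:
            raise ValidationError("individual sets differ")
        return VariantProfileMatrix(
            self.individuals,
            self.sites + other.sites,
            np.vstack([self.values, other.values]),
            np.vstack([self.masked, other.masked]),
        )


def call_profile(
    base_counts: BaseCountTable,
    min_reads: int = DEFAULT_MIN_READS,
    per_base_threshold: bool = True,
    site_classes: dict[str, str] | None = None,
) -> VariantProfileMatrix:
    """Call a single-individual profile from per-site base counts.

    At every site the percent of non-reference reads is
    ``100 * (sum of non-reference counts >= min_reads) / total reads``; base
    counts below ``min_reads`` are treated as sequencing noise and contribute
    0.  A site whose total coverage is below ``min_reads`` is masked (value
    0).  With ``per_base_threshold=False`` only the per-site total check is
    applied and every non-reference read counts.

    ``site_classes`` optionally maps coordinates to a site class label.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    frame = base_counts.frame
    sites: list[SiteRecord] = []
    pct = np.zeros(len(frame))
    masked = np.zeros(len(frame), dtype=bool)
    for i, row in enumerate(frame.itertuples(index=False)):
        coord = str(row.site)
        counts = {b: float(getattr(row, b)) for b in NUCLEOTIDES}
        total = sum(counts.values())
        nonref = {b: c for b, c in counts.items() if b != row.ref}
        if total < min_reads:
            masked[i] = True
            pct[i] = 0.0
        else:
            if per_base_threshold:
                kept = {b: c for b, c in nonref.items() if c >= min_reads}
            else:
                kept = {b: c for b, c in nonref.items() if c > 0}
            if len(kept) > 1:
                warnings.warn(
                    f"site {coord}: {len(kept)} non-reference bases above "
                    "threshold; counts summed but site treated as biallelic",
                    stacklevel=2,
                )
            pct[i] = 100.0 * sum(kept.values()) / total
        cls_ = site_classes.get(coord) if site_classes else None
        sites.append(SiteRecord(coordinate=coord, site_class=cls_))
    return VariantProfileMatrix(
        [base_counts.individual_id], sites, pct[:, None], masked[:, None]
    )


def combine_profiles(rows: Iterable[VariantProfileMatrix]) -> VariantProfileMatrix:
    """Join single-individual profiles sharing the same sites into one matrix."""
    rows = list(rows)
    if not rows:
        raise ValidationError("no profiles to combine")
    first = rows[0]
    coords = [s.coordinate for s in first.sites]
    values = []
    masked = []
    individuals = []
    for r in rows:
        if [s.coordinate for s in r.sites] != coords:
            raise ValidationError("profiles cover different sites")
        individuals.extend(r.individuals)
        values.append(r.values)
        masked.append(r.masked)
    return VariantProfileMatrix(
        individuals, first.sites, np.hstack(values), np.hstack(masked)
    )


def summarize_sites(matrix: VariantProfileMatrix) -> list[SiteSummary]:
    """One frequency-spectrum summary per site.

    A carrier is an individual with an unmasked strictly positive value.
    """
    if matrix.n_individuals == 0 or matrix.n_sites == 0:
        raise ValidationError("matrix is empty")
    out = []
    n = matrix.n_individuals
    for i, site in enumerate(matrix.sites):
        row = matrix.values[i]
        carriers = (row > 0) & ~matrix.masked[i]
        k = int(carriers.sum())
        out.append(
            SiteSummary(
                site=site,
                n_carriers=k,
                mean_pct_all=float(row.sum() / n),
                mean_pct_carriers=float(row[carriers].mean()) if k else float("nan"),
            )
        )
    return out


def summaries_frame(summaries: Iterable[SiteSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [s.site.coordinate for s in summaries],
            "class": [s.site.site_class for s in summaries],
            "n_carriers": [s.n_carriers for s in summaries],
            "mean_pct_all": [s.mean_pct_all for s in summaries],
            "mean_pct_carriers": [s.mean_pct_carriers for s in summaries],
        }
    )


# -- bundled transcriptions of the published variant tables -----------------


def _load_bundled(name: str) -> VariantProfileMatrix:
    with resources.files("mupscent.data").joinpath(name).open() as fh:
        return VariantProfileMatrix.from_frame(pd.read_csv(fh))


def load_nonsynonymous_table() -> VariantProfileMatrix:
    """Non-synonymous variant sites (11 sites x 18 mice)."""
    return _load_bundled("central_mup_nonsynonymous.csv")


def load_synonymous_table() -> VariantProfileMatrix:
    """Synonymous variant sites (22 sites x 18 mice)."""
    return _load_bundled("central_mup_synonymous.csv")


def load_combined_tables() -> VariantProfileMatrix:
    """Both site classes stacked over the shared 18 individuals."""
    return load_nonsynonymous_table().concat_sites(load_synonymous_table())
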