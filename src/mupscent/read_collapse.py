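"""Exon-read collapse and expression classification.

Amplicon / cDNA reads that completely span a short sub-region (e.g. exon 1,
96-99 bp) are grouped by exact sequence identity.  With deep coverage and a
low per-base error rate, genuine sequences form a high-depth plateau while
error-bearing reads form a low-depth tail, so the accepted set is delimited
by a sharp decline ("knee") in the depth-sorted catalog.  Proportional
representation over the accepted set corrects for depth differences between
individuals and between DNA and RNA libraries, and the RNA proportion of a
DNA sequence classifies it as expressed (>5%), weakly expressed (1-5%) or
silenced (<1%).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import MupscentError, ValidationError
from .pd_stats import TestReport, regress

EXPRESSION_CATEGORIES = ("expressed", "weak", "silenced")

#: (silenced_below, expressed_above) on the proportion scale
DEFAULT_THRESHOLDS = (0.01, 0.05)


@dataclass(frozen=True)
class ReadRecord:
    sequence: str
    depth: int


@dataclass
class ReadCatalog:
    """Unique sequences spanning one region, with read depths."""

    region: str
    records: list[ReadRecord]
    n_discarded: int = 0

    def __post_init__(self):
        seqs = [r.sequence for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValidationError("duplicate sequences in catalog")
        if any(r.depth < 1 for r in self.records):
            raise ValidationError("depths must be >= 1")

    @property
    def total_depth(self) -> int:
        return sum(r.depth for r in self.records)


@dataclass(frozen=True)
class AcceptedRecord:
    sequence: str
    depth: int
    proportion: float


@dataclass
class ExonCatalog:
    """Depth-filtered catalog: accepted true sequences plus rejected tail."""

    region: str
    accepted: list[AcceptedRecord]
    rejected: list[ReadRecord]

    def __post_init__(self):
        if self.accepted:
            total = sum(r.proportion for r in self.accepted)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError("accepted proportions must sum to 1")

    def proportions(self) -> dict[str, float]:
        return {r.sequence: r.proportion for r in self.accepted}


@dataclass(frozen=True)
class ExpressionCall:
    sequence: str
    rna_proportion: float
    category: str


def read_sequences(path, fmt: str | None = None) -> list[str]:
    """Load read sequences from FASTA or FASTQ (qualities ignored)."""
    from Bio import SeqIO

    if fmt is None:
        fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def collapse_reads(
    reads: Iterable[str],
    region: str = "region",
    length_range: tuple[int, int] | None = None,
) -> ReadCatalog:
    """Group identical reads; reads outside ``length_range`` are discarded
    with a tally.  Depth is the multiplicity of each unique sequence."""
    kept: list[str] = []
    discarded = 0
    for r in reads:
        r = r.upper()
        if length_range is not None and not (
            length_range[0] <= len(r) <= length_range[1]
        ):
            discarded += 1
        else:
            kept.append(r)
    if not kept:
        warnings.warn(f"no reads span region {region!r}", stacklevel=2)
    counts = Counter(kept)
    records = [
        ReadRecord(seq, depth)
        for seq, depth in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return ReadCatalog(region=region, records=records, n_discarded=discarded)


def call_true_sequences(
    catalog: ReadCatalog,
    min_depth_floor: int = 2,
    knee_method: str = "log_gap",
    min_log_gap: float = 1.0,
    max_fraction_cutoff: float = 0.01,
) -> ExonCatalog:
    """Separate true sequences from error artifacts by read depth.

    With ``knee_method="log_gap"`` (default) the cut sits at the largest gap
    in log10 depth between consecutive depth-sorted records, provided that
    gap exceeds ``min_log_gap`` (a 10-fold decline by default); otherwise all
    records are accepted with a "no knee found" warning.
    ``knee_method="fraction"`` instead accepts records with depth at least
    ``max_fraction_cutoff`` times the maximum depth.  Records below
    ``min_depth_floor`` are never accepted.  Proportions are renormalised
    over the accepted records.
    """
    if not catalog.records:
        raise ValidationError("catalog is empty")
    records = sorted(catalog.records, key=lambda r: (-r.depth, r.sequence))
    depths = np.array([r.depth for r in records], dtype=float)
    if knee_method == "log_gap":
        if len(records) == 1:
            cut = 1
        else:
            gaps = np.diff(-np.log10(depths))  # positive when depth drops
            k = int(np.argmax(gaps))
            if gaps[k] >= min_log_gap:
                cut = k + 1
            else:
                warnings.warn(
                    f"no knee found in {catalog.region!r} depth profile; "
                    "accepting all records",
                    stacklevel=2,
                )
                cut = len(records)
    elif knee_method == "fraction":
        cut = int(np.sum(depths >= max_fraction_cutoff * depths[0]))
    else:
        raise MupscentError(f"unknown knee method {knee_method!r}")
    accepted_raw = [r for r in records[:cut] if r.depth >= min_depth_floor]
    rejected = [r for r in records if r not in accepted_raw]
    if not accepted_raw:
        warnings.warn(
            f"all records in {catalog.region!r} fall below the depth floor",
            stacklevel=2,
        )
        return ExonCatalog(region=catalog.region, accepted=[], rejected=rejected)
    total = sum(r.depth for r in accepted_raw)
    accepted = [
        AcceptedRecord(r.sequence, r.depth, r.depth / total) for r in accepted_raw
    ]
    return ExonCatalog(region=catalog.region, accepted=accepted, rejected=rejected)


def classify_expression(
    dna_sequences: Sequence[str],
    rna_catalog: ExonCatalog,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[ExpressionCall]:
    """Classify each DNA sequence by its share of the RNA pool.

    Boundaries follow a literal reading of the category definitions:
    strictly below the lower threshold is silenced, strictly above the upper
    is expressed, and the closed interval between them (including both
    boundary values) is weak.  A DNA sequence absent from the accepted RNA
    set has proportion 0 and is silenced.
    """
    lo, hi = thresholds
    if not (0 <= lo <= hi <= 1):
        raise ValidationError("thresholds must satisfy 0 <= lo <= hi <= 1")
    rna = rna_catalog.proportions()
    calls = []
    for seq in dna_sequences:
        p = rna.get(seq, 0.0)
        if p < lo:
            cat = "silenced"
        elif p > hi:
            cat = "expressed"
        else:
            cat = "weak"
        calls.append(ExpressionCall(sequence=seq, rna_proportion=p, category=cat))
    return calls


@dataclass(frozen=True)
class ConcordanceResult:
    sequences: list[str]
    dna: np.ndarray
    rna: np.ndarray
    regression_full: TestReport
    regression_expressed: TestReport | None
    n_expressed_only: int


def dna_rna_concordance(
    dna_props: Mapping[str, float],
    rna_props: Mapping[str, float],
    expression_floor: float = 0.01,
) -> ConcordanceResult:
    """Regress RNA proportion on DNA proportion over shared sequences.

    Reported twice: over every DNA sequence (missing RNA treated as 0) and
    over the subset with RNA proportion above ``expression_floor``.
    """
    keys = sorted(dna_props)
    if not keys:
        raise ValidationError("no DNA sequences supplied")
    if not set(keys) & set(rna_props):
        raise ValidationError("no shared sequence keys between DNA and RNA")
    x = np.array([dna_props[k] for k in keys])
    y = np.array([rna_props.get(k, 0.0) for k in keys])
    full = regress(x, y)
    mask = y > expression_floor
    expressed = None
    if mask.sum() >= 3 and not math.isclose(x[mask].min(), x[mask].max()):
        expressed = regress(x[mask], y[mask])
    return ConcordanceResult(
        sequences=keys,
        dna=x,
        rna=y,
        regression_full=full,
        regression_expressed=expressed,
        n_expressed_only=int(mask.sum()),
    )
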