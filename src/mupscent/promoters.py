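"""Promoter variant / expression association (eSNP scan).

Aligned promoter sequences carry an expression category inherited from the
exon they drive.  Every polymorphic alignment column is tested for
association between carrying a non-consensus state and being silenced,
using Fisher's exact test on the 2x2 table (variant/consensus x
expressed/silenced).  Weakly expressed promoters are excluded from testing;
each non-consensus state is tested separately against the consensus by
default.  No multiple-testing correction is applied by default (raw
P < 0.05 is the working criterion); a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

GAP = "-"


@dataclass
class PromoterAlignment:
    """Equal-length gapped promoter sequences with expression categories."""

    sequences: list[str]
    categories: list[str]

    def __post_init__(self):
        if len(self.sequences) != len(self.categories):
            raise ValidationError("one category per sequence required")
        if not self.sequences:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError("aligned sequences must share one length")
        bad = set(self.categories) - {"expressed", "weak", "silenced"}
        if bad:
            raise ValidationError(f"unknown categories {sorted(bad)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, fasta_path, categories: dict[str, str]) -> "PromoterAlignment":
        """Load a gapped FASTA; ``categories`` maps record id to category."""
        from Bio import SeqIO

        seqs, cats = [], []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in categories:
                raise ValidationError(f"no expression category for {rec.id!r}")
            seqs.append(str(rec.seq))
            cats.append(categories[rec.id])
        return cls(seqs, cats)


@dataclass(frozen=True)
class ESnpReport:
    """Association of one non-consensus state at one aligned column."""

    column: int
    state: str
    consensus: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    significant: bool


def fisher_exact_2x2(counts) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    The two-sided p sums hypergeometric point probabilities no larger than
    the observed one.  A table with a zero margin admits only one outcome,
    so p = 1 by convention (with a warning).
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValidationError("counts must be non-negative integers")
        table = table.astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def scan_columns(
    alignment: PromoterAlignment,
    alpha: float = 0.05,
    gap_as_state: bool = True,
    column_mask: Sequence[int] = (),
    bh_correction: bool = False,
) -> list[ESnpReport]:
    """Fisher-test every polymorphic column for association with silencing.

    Only expressed and silenced promoters are testable (weak excluded).  The
    consensus state is the most frequent among testable rows; each other
    state forms its own 2x2 test.  Columns listed in ``column_mask`` (e.g. a
    poorly aligned poly-A tract) are skipped.  With ``bh_correction`` the
    significance flags use Benjamini-Hochberg adjusted p-values; raw
    p-values are always reported.
    """
    rows = [
        (s, c) for s, c in zip(alignment.sequences, alignment.categories)
        if c in ("expressed", "silenced")
    ]
    if len({c for _, c in rows}) < 2:
        raise ValidationError("need both expressed and silenced promoters")
    masked = set(column_mask)
    reports: list[ESnpReport] = []
    for col in range(alignment.length):
        if col in masked:
            continue
        states = [s[col] for s, _ in rows]
        if not gap_as_state:
            usable = [(st, c) for (st, (_, c)) in zip(states, rows) if st != GAP]
        else:
            usable = list(zip(states, (c for _, c in rows)))
        counts = Counter(st for st, _ in usable)
        if len(counts) < 2:
            continue  # monomorphic column
        consensus = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        for state in sorted(counts):
            if state == consensus:
                continue
            var_exp = sum(1 for st, c in usable if st == state and c == "expressed")
            var_sil = sum(1 for st, c in usable if st == state and c == "silenced")
            con_exp = sum(1 for st, c in usable if st == consensus and c == "expressed")
            con_sil = sum(1 for st, c in usable if st == consensus and c == "silenced")
            table = ((var_exp, var_sil), (con_exp, con_sil))
            p = fisher_exact_2x2(np.array(table))
            reports.append(
                ESnpReport(
                    column=col,
                    state=state,
                    consensus=consensus,
                    table=table,
                    p_value=p,
                    significant=p < alpha,
                )
            )
    if bh_correction and reports:
        ps = np.array([r.p_value for r in reports])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        reports = [
            ESnpReport(r.column, r.state, r.consensus, r.table, r.p_value,
                       bool(adj[i] < alpha))
            for i, r in enumerate(reports)
        ]
    return reports
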