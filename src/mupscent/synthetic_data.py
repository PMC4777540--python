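"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the structure of the real study system: a population
of diploid individuals, each carrying a cassette of ~30 near-identical gene
copies drawn from a small pool of isoform variants.  Each variant has a
distinctive short coding region (the stand-in for exon 1, which both
identifies the isoform and determines the protein's mass class), and each
copy may be transcriptionally silenced.  Transcript pools are proportional
to expressed copies; urine mass profiles are proportional to the transcript
mass classes plus measurement noise.  All emitted artifacts (per-site base
counts, raw reads, transcript catalogs, promoter alignments, ESI/MS-style
peak lists) are mutually consistent with the stored truth, so pipeline
outputs can be checked against known quantities.

Deliberate simplifications: one discriminating region serves as both the
expression marker and the mass determinant (the real data use exon 1 and a
separate exon-2/3 window); every variant has a unique mass class; reads are
error-bearing copies of the region with a uniform per-base error and no
quality structure; and there is no true copy-number/percentage confound
unless ``copy_number_sd`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fds_sim import SummaryStats
from .phenotypes import MassProfile, average_mass
from .profiles import BaseCountTable, SiteRecord, VariantProfileMatrix
from .read_collapse import AcceptedRecord, ExonCatalog

BASES = "ACGT"

# substitutions applied to the base protein, chosen for well-separated
# average-mass shifts (>= 5 Da) so every variant owns a mass class
_PROTEIN_SUBS = [
    ("F", "V"),  # -48.04 Da
    ("K", "E"),  # +0.94 -> too close; replaced below
    ("A", "T"),  # +30.03 Da
    ("G", "R"),  # +99.14 Da
    ("S", "F"),  # +60.10 Da
    ("L", "W"),  # +73.05 Da
    ("D", "Y"),  # +48.09 Da
    ("T", "K"),  # +27.07 Da
]
_PROTEIN_SUBS[1] = ("N", "R")  # +42.08 Da


@dataclass(frozen=True)
class GeneratorConfig:
    n_individuals: int = 18
    n_gene_copies: int = 30
    n_variants: int = 8  # haplotype pool size (variant 0 = reference)
    silencing_prob: float = 0.3
    silencing_bias: str = "none"  # "common" | "rare" | "none"
    copy_number_sd: float = 0.0
    dna_depth: int = 7000
    rna_depth: int = 5000
    read_error_rate: float = 0.001
    ms_noise_sd: float = 0.0
    n_ms_replicates: int = 2
    region_length: int = 96
    protein_length: int = 157
    seed: int = 0

    def __post_init__(self):
        for name in ("silencing_prob", "read_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.silencing_bias not in ("common", "rare", "none"):
            raise ValidationError(f"unknown silencing bias {self.silencing_bias!r}")
        if self.n_variants < 2:
            raise ValidationError("need at least two variants in the pool")
        if self.n_variants - 1 > len(_PROTEIN_SUBS):
            raise ValidationError(
                f"at most {len(_PROTEIN_SUBS) + 1} variants supported"
            )
        if self.dna_depth < 1 or self.rna_depth < 1:
            raise ValidationError("depths must be >= 1")
        if self.n_variants - 1 > self.region_length // 4:
            raise ValidationError("region too short for the requested pool")


@dataclass(frozen=True)
class Variant:
    """One member of the isoform pool."""

    index: int
    region_seq: str  # discriminating nucleotide region
    protein_seq: str  # mature protein
    mass: float  # average mass, Da
    variant_site: int | None  # region position distinguishing it (None = ref)


@dataclass
class TruthBundle:
    """Per-individual ground truth for all pipeline stages."""

    variants: list[Variant]
    individual_ids: list[str]
    copy_assignments: list[np.ndarray]  # variant index per gene copy
    silenced: list[np.ndarray]  # bool per gene copy
    dna_fractions: pd.DataFrame  # individuals x variants
    rna_fractions: pd.DataFrame
    mass_proportions: pd.DataFrame  # individuals x mass classes


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _build_pool(config: GeneratorConfig, rng: np.random.Generator) -> list[Variant]:
    base_region = _random_sequence(rng, config.region_length, BASES)
    # base protein built from residues present in the substitution table so
    # every planned exchange has a target position
    residues = "ACDEFGHIKLMNPQRSTVWY"
    base_protein = _random_sequence(rng, config.protein_length, residues)
    # guarantee each substitution's source residue occurs at a unique position
    protein = list(base_protein)
    for k, (src, _dst) in enumerate(_PROTEIN_SUBS[: config.n_variants - 1]):
        protein[10 + 3 * k] = src
    base_protein = "".join(protein)

    # distinct region positions, one per non-reference variant
    positions = rng.choice(config.region_length, size=config.n_variants - 1,
                           replace=False)
    pool = [
        Variant(0, base_region, base_protein, average_mass(base_protein), None)
    ]
    for k in range(1, config.n_variants):
        pos = int(positions[k - 1])
        old = base_region[pos]
        new = BASES[(BASES.index(old) + 1 + (k % 3)) % 4]
        region = base_region[:pos] + new + base_region[pos + 1 :]
        src, dst = _PROTEIN_SUBS[k - 1]
        ppos = 10 + 3 * (k - 1)
        prot = base_protein[:ppos] + dst + base_protein[ppos + 1 :]
        pool.append(Variant(k, region, prot, average_mass(prot), pos))
    return pool


class SyntheticPopulation:
    """A generated population plus emitters for every stage's input format."""

    def __init__(self, config: GeneratorConfig, truth: TruthBundle):
        self.config = config
        self.truth = truth
        self._rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1_000_003])
        )

    # -- truth-level matrices -------------------------------------------

    def _fraction_matrix(self, fractions: pd.DataFrame) -> VariantProfileMatrix:
        """Percent non-reference reads per variant site, noise-free."""
        variants = [v for v in self.truth.variants if v.variant_site is not None]
        sites = [
            SiteRecord(coordinate=f"region:{v.variant_site + 1}",
                       site_class="nonsynonymous")
            for v in variants
        ]
        values = np.array(
            [100.0 * fractions[v.index].to_numpy() for v in variants]
        )
        return VariantProfileMatrix(self.truth.individual_ids, sites, values)

    def true_dna_matrix(self) -> VariantProfileMatrix:
        return self._fraction_matrix(self.truth.dna_fractions)

    def true_rna_matrix(self) -> VariantProfileMatrix:
        return self._fraction_matrix(self.truth.rna_fractions)

    # -- stage inputs ----------------------------------------------------

    def base_count_table(self, individual: str) -> BaseCountTable:
        """DNA pileup over the discriminating region with sequencing error."""
        cfg = self.config
        i = self.truth.individual_ids.index(individual)
        fractions = self.truth.dna_fractions.iloc[i]
        e = cfg.read_error_rate
        rows = []
        region_len = cfg.region_length
        ref = self.truth.variants[0].region_seq
        # per-position mixture of true bases over copies
        for pos in range(region_len):
            mix = {b: 0.0 for b in BASES}
            for v in self.truth.variants:
                mix[v.region_seq[pos]] += fractions[v.index]
            probs = np.zeros(4)
            for bi, b in enumerate(BASES):
                probs[bi] = sum(
                    mix[t] * ((1 - e) if b == t else e / 3) for t in BASES
                )
            counts = self._rng.multinomial(cfg.dna_depth, probs / probs.sum())
            rows.append(
                {"site": pos + 1, "ref": ref[pos],
                 **{b: int(c) for b, c in zip(BASES, counts)}}
            )
        return BaseCountTable(individual, pd.DataFrame(rows))

    def region_reads(self, individual: str, kind: str = "dna") -> list[str]:
        """Raw reads spanning the region, with per-base error."""
        cfg = self.config
        i = self.truth.individual_ids.index(individual)
        if kind == "dna":
            fractions = self.truth.dna_fractions.iloc[i]
            depth = cfg.dna_depth
        elif kind == "rna":
            fractions = self.truth.rna_fractions.iloc[i]
            depth = cfg.rna_depth
        else:
            raise ValidationError(f"unknown read kind {kind!r}")
        probs = fractions.to_numpy(dtype=float)
        counts = self._rng.multinomial(depth, probs / probs.sum())
        reads = []
        for v, n in zip(self.truth.variants, counts):
            for _ in range(n):
                seq = list(v.region_seq)
                n_err = self._rng.binomial(len(seq), cfg.read_error_rate)
                for pos in self._rng.choice(len(seq), size=n_err, replace=False):
                    seq[pos] = BASES[
                        (BASES.index(seq[pos]) + 1 + self._rng.integers(0, 3)) % 4
                    ]
                reads.append("".join(seq))
        self._rng.shuffle(reads)
        return reads

    def rna_catalog(self, individual: str, exact: bool = False) -> ExonCatalog:
        """Accepted transcript catalog for one individual.

        ``exact`` bypasses sampling noise and reports the true RNA fractions.
        """
        cfg = self.config
        i = self.truth.individual_ids.index(individual)
        fractions = self.truth.rna_fractions.iloc[i]
        present = [v for v in self.truth.variants if fractions[v.index] > 0]
        if exact:
            props = np.array([fractions[v.index] for v in present])
        else:
            counts = self._rng.multinomial(
                cfg.rna_depth, np.array([fractions[v.index] for v in present])
            )
            present = [v for v, c in zip(present, counts) if c > 0]
            counts = counts[counts > 0]
            props = counts / counts.sum()
        accepted = [
            AcceptedRecord(v.region_seq, max(1, int(round(p * cfg.rna_depth))), p)
            for v, p in zip(present, props / props.sum())
        ]
        return ExonCatalog(region="region", accepted=accepted, rejected=[])

    def mass_map(self) -> dict[str, float]:
        """Region sequence -> mature protein average mass (Da)."""
        return {v.region_seq: v.mass for v in self.truth.variants}

    def mass_bins(self) -> list[float]:
        return sorted({v.mass for v in self.truth.variants})

    def peak_list(
        self, individual: str, replicate: int = 0
    ) -> list[tuple[float, float]]:
        """Deconvolved-spectrum peak list: the individual's true mass-class
        proportions times a scale, with multiplicative Gaussian noise."""
        cfg = self.config
        props = self.truth.mass_proportions.loc[individual]
        peaks = []
        for mass, p in props.items():
            if p <= 0:
                continue
            noise = 1.0 + cfg.ms_noise_sd * self._rng.standard_normal()
            peaks.append((float(mass), max(0.0, 1000.0 * p * noise)))
        if not any(h > 0 for _, h in peaks):  # pathological noise draw
            peaks = [(float(m), 1000.0 * p) for m, p in props.items() if p > 0]
        return peaks

    def observed_profiles(self) -> list[MassProfile]:
        """One observed profile per (individual, replicate)."""
        out = []
        for ind in self.truth.individual_ids:
            for r in range(self.config.n_ms_replicates):
                peaks = self.peak_list(ind, r)
                total = sum(h for _, h in peaks)
                out.append(
                    MassProfile(
                        individual_id=ind,
                        bins=np.array(sorted(m for m, _ in peaks)),
                        proportions=np.array(
                            [h / total for m, h in sorted(peaks)]
                        ),
                        source="observed_ms",
                        sample_id=f"{ind}_rep{r}",
                        collection_day=float(r * 7),
                    )
                )
        return out

    def promoter_alignment(
        self,
        n_planted: int = 3,
        n_noise_columns: int = 50,
        planted_effect: float = 0.85,
        background_rate: float = 0.05,
    ) -> tuple[list[str], list[str], list[int]]:
        """Aligned promoter sequences, expression categories and the planted
        silencing-associated column indices.

        One promoter per (individual, unique expressed-or-silenced variant);
        silenced promoters carry the alternative base at each planted column
        with probability ``planted_effect``, expressed promoters with
        probability ``background_rate``; noise columns vary at the
        background rate regardless of category.
        """
        rng = self._rng
        length = n_planted + n_noise_columns
        base = _random_sequence(rng, length, BASES)
        planted = list(range(n_planted))  # leading columns are the planted ones
        seqs, cats = [], []
        for i, ind in enumerate(self.truth.individual_ids):
            copies = self.truth.copy_assignments[i]
            silenced = self.truth.silenced[i]
            for v in np.unique(copies):
                expressed_any = bool((~silenced[copies == v]).any())
                cat = "expressed" if expressed_any else "silenced"
                seq = list(base)
                for col in range(length):
                    if col in planted:
                        p = background_rate if cat == "expressed" else planted_effect
                    else:
                        p = background_rate
                    if rng.random() < p:
                        seq[col] = BASES[(BASES.index(seq[col]) + 1) % 4]
                seqs.append("".join(seq))
                cats.append(cat)
        return seqs, cats, planted

    def write(self, out_dir) -> None:
        """Write every stage input as plain-text files under ``out_dir``."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.true_dna_matrix().to_csv(os.path.join(out_dir, "dna_matrix.csv"))
        self.true_rna_matrix().to_csv(os.path.join(out_dir, "rna_matrix.csv"))
        for ind in self.truth.individual_ids:
            self.base_count_table(ind).frame.to_csv(
                os.path.join(out_dir, f"counts_{ind}.tsv"), sep="\t", index=False
            )
            with open(os.path.join(out_dir, f"reads_{ind}.fasta"), "w") as fh:
                for k, read in enumerate(self.region_reads(ind, "rna")):
                    fh.write(f">{ind}_r{k}\n{read}\n")
            for r in range(self.config.n_ms_replicates):
                pd.DataFrame(
                    self.peak_list(ind, r), columns=["mass_da", "intensity"]
                ).to_csv(
                    os.path.join(out_dir, f"peaks_{ind}_rep{r}.csv"), index=False
                )
        seqs, cats, planted = self.promoter_alignment()
        with open(os.path.join(out_dir, "promoters.fasta"), "w") as fh:
            for k, s in enumerate(seqs):
                fh.write(f">prom{k}\n{s}\n")
        pd.DataFrame(
            {"id": [f"prom{k}" for k in range(len(seqs))], "category": cats}
        ).to_csv(os.path.join(out_dir, "promoter_categories.csv"), index=False)


def generate_population(config: GeneratorConfig) -> SyntheticPopulation:
    """Draw a population consistent with the configured architecture.

    Copies are drawn from a Dirichlet-weighted pool so variants span common
    and rare population frequencies; silencing is applied per copy with the
    configured bias (preferentially hitting variants of high or low
    population frequency, or uniformly).  RNA fractions are the DNA copy
    fractions restricted to unsilenced copies and renormalised; mass
    proportions pool RNA fractions by protein mass class.
    """
    rng = np.random.default_rng(config.seed)
    pool = _build_pool(config, rng)
    ids = [f"IND{301 + i}" for i in range(config.n_individuals)]

    # population-level variant weights: a few common, several rare
    weights = rng.dirichlet(np.linspace(3.0, 0.3, config.n_variants))
    order = np.argsort(weights)[::-1]
    pop_freq = np.empty(config.n_variants)
    pop_freq[order] = np.sort(weights)[::-1]
    common = pop_freq >= np.median(pop_freq)
    # for the "rare" bias: concerted silencing shared by every individual
    variant_silenced = (
        np.random.default_rng(np.random.SeedSequence([config.seed, 77])).random(
            config.n_variants
        )
        < config.silencing_prob
    ) & ~common

    copy_assignments, silenced_states = [], []
    dna_rows, rna_rows = [], []
    for i in range(config.n_individuals):
        n_copies = config.n_gene_copies
        if config.copy_number_sd > 0:
            n_copies = max(
                6, int(round(rng.normal(config.n_gene_copies, config.copy_number_sd)))
            )
        copies = rng.choice(config.n_variants, size=n_copies, p=pop_freq)
        if config.silencing_bias == "none":
            # promoter state independent per gene copy
            silenced = rng.random(n_copies) < config.silencing_prob
        elif config.silencing_bias == "common":
            # individuals silence different *shared* variants: the silencing
            # decision is per (individual, common variant), hitting all of
            # that individual's copies of the variant
            sil_var = (rng.random(config.n_variants) < config.silencing_prob) & common
            silenced = sil_var[copies]
        else:  # rare: a population-wide silencing allele on rare variants
            silenced = variant_silenced[copies]
        if silenced.all():  # keep at least one transcribed copy
            silenced[rng.integers(0, n_copies)] = False
        copy_assignments.append(copies)
        silenced_states.append(silenced)
        dna = np.bincount(copies, minlength=config.n_variants) / n_copies
        expressed = copies[~silenced]
        rna = np.bincount(expressed, minlength=config.n_variants) / expressed.size
        dna_rows.append(dna)
        rna_rows.append(rna)

    dna_fr = pd.DataFrame(dna_rows, index=ids, columns=range(config.n_variants))
    rna_fr = pd.DataFrame(rna_rows, index=ids, columns=range(config.n_variants))
    masses = sorted({v.mass for v in pool})
    mass_rows = []
    for i in range(config.n_individuals):
        row = {m: 0.0 for m in masses}
        for v in pool:
            row[v.mass] += rna_fr.iloc[i][v.index]
        mass_rows.append(row)
    mass_props = pd.DataFrame(mass_rows, index=ids)

    truth = TruthBundle(
        variants=pool,
        individual_ids=ids,
        copy_assignments=copy_assignments,
        silenced=silenced_states,
        dna_fractions=dna_fr,
        rna_fractions=rna_fr,
        mass_proportions=mass_props,
    )
    return SyntheticPopulation(config, truth)


def generate_observed_stats(matrix: VariantProfileMatrix) -> SummaryStats:
    """Map an empirical variant-profile matrix to the simulator's summary
    statistics: class-wise site counts and the mean over sites of the
    across-individual mean read fraction (percent / 100)."""
    from .profiles import summarize_sites

    if matrix.n_sites == 0 or matrix.n_individuals == 0:
        raise ValidationError("empty matrix")
    if not (matrix.values > 0).any():
        raise ValidationError("matrix has no variation")
    summaries = summarize_sites(matrix)
    ns = [s for s in summaries if s.site.site_class == "nonsynonymous"]
    syn = [s for s in summaries if s.site.site_class == "synonymous"]

    def _mean(group):
        if not group:
            return 0.0, False
        return float(np.mean([g.mean_pct_all for g in group]) / 100.0), True

    mf_ns, ns_def = _mean(ns)
    mf_s, s_def = _mean(syn)
    return SummaryStats(
        s_ns=len(ns),
        s_s=len(syn),
        mean_freq_ns=mf_ns,
        mean_freq_s=mf_s,
        mean_freq_ns_defined=ns_def,
        mean_freq_s_defined=s_def,
    )
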