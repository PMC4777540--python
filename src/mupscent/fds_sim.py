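"""Forward-time Wright-Fisher simulation of a multigene pheromone cassette
under negative frequency-dependent selection.

Each diploid individual carries two haplotypes, each a cassette of
``n_genes`` near-identical paralogs (15 by default, fixed: no copy-number
mutation).  Every gene copy tracks binary allelic states at ``n_ns_sites``
selected non-synonymous positions and ``n_s_sites`` neutral synonymous
positions, homologous across paralogs.  Per generation:

1. *Fitness.*  For each individual and each non-synonymous position the
   within-genome allele frequency f is the fraction of its 2 x n_genes
   copies carrying the mutation.  The individual's distance d is the summed
   absolute deviation of its f values from the population means.  Fitness is
   linear in d: the maximally distinct individual has w = 1, an exactly
   average individual has w = 1 - s.  Rare pheromone profiles are favoured.
2. *Reproduction.*  N offspring each draw two parents with probability
   proportional to w (selfing allowed); each transmitted cassette copies one
   parental haplotype, or with probability ``rec_rate`` a crossover of the
   two at a uniform inter-site breakpoint.
3. *Gene conversion.*  Gene copies initiate ectopic conversion at rate
   ``gc_rate`` per copy; the donor is uniform among the other 2 x n_genes-1
   copies of the same genome (intra- or inter-chromosomal); the tract starts
   uniformly, has geometric length (mean ``gc_tract_mean``), is truncated at
   the gene end, and copies homologous coordinates non-reciprocally.
4. *Mutation.*  Every site flips state with probability ``mu``
   (biallelic, back-mutation allowed).

Populations start monomorphic and run for 10N generations (burn-in and run
combined).  Summary statistics mirror the empirical read-percentage
representation: segregating-site counts in an 18-individual sample and the
mean within-genome frequency of segregating non-synonymous and synonymous
mutations.

The generation kernel is compiled with numba; a simulation is fully
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .errors import ValidationError


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults follow the central-Mup model."""

    N: int = 200
    s: float = 0.0
    n_genes: int = 15
    n_ns_sites: int = 15
    n_s_sites: int = 102
    mu: float = 3e-6
    gc_rate: float = 1e-4
    gc_tract_mean: float = 50.0
    rec_rate: float = 5e-6
    generations: int | None = None  # 10N when None
    sample_size: int = 18
    seed: int = 0
    apply_fitness: bool = True  # False skips the fitness computation entirely

    def __post_init__(self):
        for name in ("s", "mu", "gc_rate", "rec_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.N < 1 or self.n_genes < 1:
            raise ValidationError("N and n_genes must be positive")
        if self.n_ns_sites < 0 or self.n_s_sites < 0:
            raise ValidationError("site counts must be non-negative")
        if self.n_ns_sites > 64:
            raise ValidationError("at most 64 selected positions supported")
        if self.gc_tract_mean < 1:
            raise ValidationError("gc_tract_mean must be >= 1")
        if self.generations is not None and self.generations < 1:
            raise ValidationError("generations must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.n_ns_sites + self.n_s_sites

    @property
    def run_generations(self) -> int:
        return 10 * self.N if self.generations is None else self.generations


@dataclass(frozen=True)
class SummaryStats:
    """The four statistics regressed in the ABC fit."""

    s_ns: int
    s_s: int
    mean_freq_ns: float
    mean_freq_s: float
    mean_freq_ns_defined: bool = True
    mean_freq_s_defined: bool = True

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.s_ns, self.s_s, self.mean_freq_ns, self.mean_freq_s], dtype=float
        )

    NAMES = ("s_ns", "s_s", "mean_freq_ns", "mean_freq_s")


def initial_state(config: SimConfig) -> np.ndarray:
    """Monomorphic all-ancestral population, shape (N, 2, n_genes, n_sites)."""
    return np.zeros(
        (config.N, 2, config.n_genes, config.n_sites), dtype=np.uint8
    )


# Genomes are bit-packed inside the kernel: site l of a gene copy lives in
# bit (l & 63) of uint64 word (l >> 6), so a 117-site copy is two words and
# the per-generation genome copy stays cache-friendly.

_ONE = np.uint64(1)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


def _pack(state: np.ndarray) -> np.ndarray:
    N, two, G, L = state.shape
    W = (L + 63) // 64
    packed = np.zeros((N, two, G, W), dtype=np.uint64)
    for l in range(L):
        packed[:, :, :, l >> 6] |= state[:, :, :, l].astype(np.uint64) << np.uint64(
            l & 63
        )
    return packed


def _unpack(packed: np.ndarray, L: int) -> np.ndarray:
    N, two, G, _ = packed.shape
    state = np.empty((N, two, G, L), dtype=np.uint8)
    for l in range(L):
        state[:, :, :, l] = (packed[:, :, :, l >> 6] >> np.uint64(l & 63)) & _ONE
    return state


@njit(cache=True)
def _evolve_kernel(
    geno, L, n_ns, s, mu, gc_rate, gc_p, rec_rate, n_gens, apply_fitness, seed
):  # pragma: no cover - exercised through evolve()
    np.random.seed(seed)
    N, _, G, W = geno.shape
    off = np.empty_like(geno)
    f = np.empty((N, max(n_ns, 1)))
    fbar = np.empty(max(n_ns, 1))
    cnt_buf = np.empty(max(n_ns, 1), dtype=np.int64)
    d = np.empty(N)
    cumw = np.empty(N)
    copies = 2.0 * G
    n_copy_slots = N * 2 * G
    n_site_slots = N * 2 * G * L
    one = np.uint64(1)

    for _gen in range(n_gens):
        # --- fitness ---------------------------------------------------
        uniform = True
        if apply_fitness and s > 0.0 and n_ns > 0 and n_ns <= 64:
            # NS sites are bits 0..n_ns-1 of word 0; iterate set bits only
            if n_ns == 64:
                ns_mask = np.uint64(0xFFFFFFFFFFFFFFFF)
            else:
                ns_mask = (one << np.uint64(n_ns)) - one
            for k in range(n_ns):
                fbar[k] = 0.0
            for i in range(N):
                for k in range(n_ns):
                    cnt_buf[k] = 0
                for c in range(2):
                    for g in range(G):
                        w = geno[i, c, g, 0] & ns_mask
                        while w != np.uint64(0):
                            lsb = w & (~w + one)
                            k = 0
                            t = lsb
                            if (t & np.uint64(0xFFFFFFFF)) == np.uint64(0):
                                k += 32
                                t >>= np.uint64(32)
                            if (t & np.uint64(0xFFFF)) == np.uint64(0):
                                k += 16
                                t >>= np.uint64(16)
                            if (t & np.uint64(0xFF)) == np.uint64(0):
                                k += 8
                                t >>= np.uint64(8)
                            if (t & np.uint64(0xF)) == np.uint64(0):
                                k += 4
                                t >>= np.uint64(4)
                            if (t & np.uint64(0x3)) == np.uint64(0):
                                k += 2
                                t >>= np.uint64(2)
                            if (t & np.uint64(0x1)) == np.uint64(0):
                                k += 1
                            cnt_buf[k] += 1
                            w ^= lsb
                for k in range(n_ns):
                    fi = cnt_buf[k] / copies
                    f[i, k] = fi
                    fbar[k] += fi
            for k in range(n_ns):
                fbar[k] /= N
            dmax = 0.0
            for i in range(N):
                tot = 0.0
                for k in range(n_ns):
                    tot += abs(f[i, k] - fbar[k])
                d[i] = tot
                if tot > dmax:
                    dmax = tot
            if dmax > 0.0:
                uniform = False
                acc = 0.0
                for i in range(N):
                    acc += 1.0 - s + s * d[i] / dmax
                    cumw[i] = acc
        if uniform:
            for i in range(N):
                cumw[i] = i + 1.0

        total_w = cumw[N - 1]

        # --- reproduction ----------------------------------------------
        for i in range(N):
            for c in range(2):
                u = np.random.random() * total_w
                p = np.searchsorted(cumw, u)
                if p >= N:
                    p = N - 1
                h = 0 if np.random.random() < 0.5 else 1
                if rec_rate > 0.0 and np.random.random() < rec_rate:
                    # crossover of the two parental cassettes at a uniform
                    # inter-site breakpoint over the linearised cassette
                    bp = 1 + int(np.random.random() * (G * L - 1))
                    for g in range(G):
                        for w in range(W):
                            off[i, c, g, w] = np.uint64(0)
                    for g in range(G):
                        for l in range(L):
                            hh = h if g * L + l < bp else 1 - h
                            bit = (geno[p, hh, g, l >> 6] >> np.uint64(l & 63)) & one
                            if bit:
                                off[i, c, g, l >> 6] |= one << np.uint64(l & 63)
                else:
                    for g in range(G):
                        for w in range(W):
                            off[i, c, g, w] = geno[p, h, g, w]

        # --- ectopic gene conversion ------------------------------------
        if gc_rate > 0.0 and G * 2 > 1:
            n_events = np.random.binomial(n_copy_slots, gc_rate)
            for _e in range(n_events):
                slot = int(np.random.random() * n_copy_slots)
                i = slot // (2 * G)
                rem = slot % (2 * G)
                c = rem // G
                g = rem % G
                j = int(np.random.random() * (2 * G - 1))
                if j >= rem:
                    j += 1
                dc = j // G
                dg = j % G
                start = int(np.random.random() * L)
                length = np.random.geometric(gc_p)
                end = start + length
                if end > L:
                    end = L
                for l in range(start, end):
                    wd = l >> 6
                    mask = one << np.uint64(l & 63)
                    if off[i, dc, dg, wd] & mask:
                        off[i, c, g, wd] |= mask
                    else:
                        off[i, c, g, wd] &= ~mask

        # --- mutation ----------------------------------------------------
        if mu > 0.0:
            n_mut = np.random.binomial(n_site_slots, mu)
            for _e in range(n_mut):
                slot = int(np.random.random() * n_site_slots)
                i = slot // (2 * G * L)
                rem = slot % (2 * G * L)
                c = rem // (G * L)
                rem2 = rem % (G * L)
                g = rem2 // L
                l = rem2 % L
                off[i, c, g, l >> 6] ^= one << np.uint64(l & 63)

        geno, off = off, geno
    return geno


def evolve(
    state: np.ndarray, config: SimConfig, n_generations: int, seed: int
) -> np.ndarray:
    """Evolve ``state`` for ``n_generations``; returns a new array."""
    if state.shape != (config.N, 2, config.n_genes, config.n_sites):
        raise ValidationError(
            f"state shape {state.shape} does not match config "
            f"({config.N}, 2, {config.n_genes}, {config.n_sites})"
        )
    if n_generations < 0:
        raise ValidationError("n_generations must be >= 0")
    if n_generations == 0:
        return state.copy()
    gc_p = 1.0 / config.gc_tract_mean
    packed = _evolve_kernel(
        _pack(np.ascontiguousarray(state, dtype=np.uint8)),
        config.n_sites,
        config.n_ns_sites,
        float(config.s),
        float(config.mu),
        float(config.gc_rate),
        gc_p,
        float(config.rec_rate),
        int(n_generations),
        config.apply_fitness,
        int(seed) % (2**31 - 1),
    )
    return _unpack(packed, config.n_sites)


def step_generation(
    state: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Advance the population by one generation (fitness, reproduction,
    conversion, mutation); a pure function of state and rng."""
    return evolve(state, config, 1, int(rng.integers(0, 2**31 - 1)))


def fitness_vector(state: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-individual fitness under the distance-from-the-mean rule.

    w = 1 - s + s * d / d_max, so the maximally distinct individual has
    w = 1 and an exactly average one w = 1 - s; when all individuals are
    identical (d_max = 0) fitness is uniform at 1.
    """
    n_ns = config.n_ns_sites
    if n_ns == 0 or config.s == 0.0:
        return np.ones(state.shape[0])
    f = state[:, :, :, :n_ns].mean(axis=(1, 2))  # (N, n_ns) within-genome freqs
    d = np.abs(f - f.mean(axis=0)).sum(axis=1)
    dmax = d.max()
    if dmax == 0.0:
        return np.ones(state.shape[0])
    return 1.0 - config.s + config.s * d / dmax


def allele_frequencies(state: np.ndarray) -> np.ndarray:
    """Population allele frequency per site over all gene copies."""
    return state.mean(axis=(0, 1, 2))


def summary_stats(
    state: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> SummaryStats:
    """Sample ``sample_size`` individuals without replacement and compute the
    segregating-site counts and mean within-genome frequencies.

    A position is segregating if both alleles occur among the sampled
    2 x n_genes x sample_size copies.  The mean frequency averages, over
    segregating positions only, the sample-average within-genome frequency;
    with no segregating positions it is reported as 0 and flagged undefined.
    """
    N = state.shape[0]
    if N < config.sample_size:
        raise ValidationError("population smaller than sample_size")
    idx = rng.choice(N, size=config.sample_size, replace=False)
    sample = state[idx]  # (n, 2, G, L)
    n_ns = config.n_ns_sites
    per_ind_freq = sample.mean(axis=(1, 2))  # (n, L) within-genome frequencies
    totals = sample.sum(axis=(0, 1, 2))  # copies carrying the mutation per site
    n_copies = sample.shape[0] * 2 * sample.shape[2]
    segregating = (totals > 0) & (totals < n_copies)
    seg_ns = segregating[:n_ns]
    seg_s = segregating[n_ns:]
    mean_site_freq = per_ind_freq.mean(axis=0)

    def _mean(seg_mask, offset):
        if not seg_mask.any():
            return 0.0, False
        sel = np.flatnonzero(seg_mask) + offset
        return float(mean_site_freq[sel].mean()), True

    mf_ns, ns_def = _mean(seg_ns, 0)
    mf_s, s_def = _mean(seg_s, n_ns)
    return SummaryStats(
        s_ns=int(seg_ns.sum()),
        s_s=int(seg_s.sum()),
        mean_freq_ns=mf_ns,
        mean_freq_s=mf_s,
        mean_freq_ns_defined=ns_def,
        mean_freq_s_defined=s_def,
    )


def run_simulation(config: SimConfig) -> SummaryStats:
    """Burn a monomorphic population for 10N generations (or
    ``config.generations``) and return the sample summary statistics."""
    if config.N < config.sample_size:
        raise ValidationError(
            f"N={config.N} smaller than sample_size={config.sample_size}"
        )
    ss = np.random.SeedSequence(config.seed)
    kernel_seed, sample_seed = ss.generate_state(2)
    state = initial_state(config)
    state = evolve(state, config, config.run_generations, int(kernel_seed))
    rng = np.random.default_rng(int(sample_seed))
    return summary_stats(state, config, rng)


def run_replicates(config: SimConfig, n_reps: int) -> list[SummaryStats]:
    """Independent replicate runs with seeds derived from ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_reps)
    return [run_simulation(replace(config, seed=int(s))) for s in seeds]
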