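"""Haplotype phasing for low-SNP genes via an EM haplotype-frequency model.

Genes with at most ``max_snps`` SNPs (default 9) are phased by maximum
likelihood under random mating: the Excoffier-Slatkin EM algorithm
estimates population haplotype frequencies, distributing each multi-site
genotype's probability over the haplotype pairs compatible with it, and
each individual is then assigned its maximum-posterior compatible pair
("best guess" diplotype).  Missing genotypes at a site are marginalised
over both alleles.  This is a frequency-based stand-in for coalescent
phasing tools; externally phased reconstructions can be supplied through
:func:`popexpr.io.read_phased_haplotypes` instead.

The diplotype (unordered haplotype pair) label of each individual defines
the "haplotype" factor used by the expression ANOVA; rare diplotypes are
merged into a single bucket to keep the factor estimable.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from .datatypes import (
    MISSING,
    DiplotypeAssignment,
    GeneSNPTable,
    ValidationError,
    canonical_diplotype,
)

MAX_SNPS_DEFAULT = 9
EM_TOL = 1e-8
EM_MAX_ITER = 500

_SITE_OPTIONS = {
    0: (((0, 0),)),
    1: ((0, 1), (1, 0)),
    2: (((1, 1),)),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


def compatible_pairs(genotype: np.ndarray) -> list[tuple[str, str, int]]:
    """All unordered haplotype pairs compatible with one genotype vector.

    Returns ``(hap_a, hap_b, c)`` with ``hap_a <= hap_b`` and ``c`` = 2 for
    heterozygous pairs, 1 for homozygous ones (the ordered-pair
    multiplicity in the HWE likelihood).  Missing sites contribute every
    allele combination.
    """
    options = [_SITE_OPTIONS[int(g)] for g in genotype]
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str, int]] = []
    for combo in itertools.product(*options):
        h1 = "".join(str(a) for a, _ in combo)
        h2 = "".join(str(b) for _, b in combo)
        pair = canonical_diplotype(h1, h2)
        if pair not in seen:
            seen.add(pair)
            out.append((pair[0], pair[1], 1 if h1 == h2 else 2))
    return out


def em_haplotype_frequencies(
    pair_lists: list[list[tuple[str, str, int]]],
    init_freqs: dict[str, float] | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[dict[str, float], float, list[float]]:
    """One EM run over the pooled individuals' compatible-pair lists.

    Returns (frequencies, final log-likelihood, per-iteration
    log-likelihood trajectory).  The trajectory is checked to be
    non-decreasing (EM guarantee); a decrease beyond round-off raises.
    """
    haplotypes = sorted({h for pairs in pair_lists for a, b, _ in pairs for h in (a, b)})
    if not haplotypes:
        raise ValidationError("empty haplotype pool: no individuals to phase")
    index = {h: i for i, h in enumerate(haplotypes)}
    k = len(haplotypes)
    if init_freqs is None:
        freqs = np.full(k, 1.0 / k)
    else:
        freqs = np.array([init_freqs.get(h, 0.0) for h in haplotypes])
        freqs = freqs / freqs.sum()

    # pre-index pairs once: (idx_a, idx_b, c) per individual
    indexed = [
        [(index[a], index[b], c) for a, b, c in pairs] for pairs in pair_lists
    ]
    n = len(indexed)
    trajectory: list[float] = []
    ll = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(k)
        new_ll = 0.0
        for pairs in indexed:
            w = np.array([c * freqs[a] * freqs[b] for a, b, c in pairs])
            total = w.sum()
            if total <= 0:
                # degenerate start: reseed this individual uniformly
                w = np.ones(len(pairs))
                total = w.sum()
                new_ll += -np.inf
            else:
                new_ll += np.log(total)
            w /= total
            for (a, b, _), wi in zip(pairs, w):
                counts[a] += wi
                counts[b] += wi
        if np.isfinite(ll) and new_ll < ll - 1e-9 * max(1.0, abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased: {ll} -> {new_ll}"
            )
        trajectory.append(new_ll)
        new_freqs = counts / (2 * n)
        delta = np.abs(new_freqs - freqs).max()
        freqs, ll = new_freqs, new_ll
        if delta < tol:
            break
    return dict(zip(haplotypes, freqs)), float(ll), trajectory


def phase_gene_em(
    table: GeneSNPTable,
    max_snps: int = MAX_SNPS_DEFAULT,
    n_restarts: int = 5,
    seed: int = 0,
) -> DiplotypeAssignment:
    """Phase one gene: EM haplotype frequencies, then max-posterior diplotypes.

    The best of ``n_restarts`` EM runs (first from uniform frequencies,
    the rest from random Dirichlet starts) by log-likelihood is kept.
    Posterior ties are broken by lexicographic pair label.
    """
    if table.n_snps < 1:
        raise ValidationError(f"{table.gene_id}: no SNPs to phase")
    if table.n_snps > max_snps:
        raise ValidationError(
            f"{table.gene_id}: {table.n_snps} SNPs exceeds phasing limit {max_snps}"
        )
    pair_lists = [compatible_pairs(table.genotypes[:, i]) for i in range(len(table.sample_ids))]
    haplotypes = sorted({h for pairs in pair_lists for a, b, _ in pairs for h in (a, b)})

    rng = np.random.default_rng(seed)
    best: tuple[dict[str, float], float] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            init = None
        else:
            draw = rng.dirichlet(np.ones(len(haplotypes)))
            init = dict(zip(haplotypes, draw))
        freqs, ll, _ = em_haplotype_frequencies(pair_lists, init)
        if best is None or ll > best[1]:
            best = (freqs, ll)
    freqs, ll = best

    pairs_out: dict[str, tuple[str, str]] = {}
    posteriors: dict[str, float] = {}
    for sample_id, pairs in zip(table.sample_ids, pair_lists):
        w = np.array([c * freqs[a] * freqs[b] for a, b, c in pairs])
        total = w.sum()
        post = w / total if total > 0 else np.full(len(pairs), 1.0 / len(pairs))
        # argmax with lexicographic tie-break on the canonical pair label
        best_i = min(
            range(len(pairs)),
            key=lambda i: (-post[i], (pairs[i][0], pairs[i][1])),
        )
        pairs_out[sample_id] = (pairs[best_i][0], pairs[best_i][1])
        posteriors[sample_id] = float(post[best_i])
    return DiplotypeAssignment(
        gene_id=table.gene_id,
        pairs=pairs_out,
        posteriors=posteriors,
        hap_freqs=_renormalise(freqs),
        log_likelihood=ll,
    )


def _renormalise(freqs: dict[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    return {h: f / total for h, f in freqs.items()}


RARE_LABEL = "rare"


def diplotype_factor(
    assignment: DiplotypeAssignment, min_group_size: int = 2
) -> dict[str, str] | None:
    """Per-sample categorical haplotype-pair factor for the ANOVA.

    Levels are canonical ``"hapA|hapB"`` labels; levels carried by fewer
    than ``min_group_size`` individuals are merged into a single
    ``"rare"`` level.  Returns None (gene dropped from haplotype ANOVA)
    when fewer than 2 levels remain.
    """
    labels = {s: f"{a}|{b}" for s, (a, b) in assignment.pairs.items()}
    sizes = Counter(labels.values())
    merged = {
        s: (lab if sizes[lab] >= min_group_size else RARE_LABEL)
        for s, lab in labels.items()
    }
    if len(set(merged.values())) < 2:
        return None
    return merged


def exhaustive_ml_frequencies(
    pair_lists: list[list[tuple[str, str, int]]],
    grid_points: int = 24,
    n_starts: int = 30,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """Maximum-likelihood haplotype frequencies by direct search.

    Independent of the EM path: a simplex grid scan (for pools of at most
    4 haplotypes) plus many multistart Nelder-Mead refinements in softmax
    coordinates.  Intended as an oracle for tiny instances (<= 3 SNPs,
    <= 6 individuals) in tests, not for production phasing.
    """
    from scipy.optimize import minimize

    haplotypes = sorted({h for pairs in pair_lists for a, b, _ in pairs for h in (a, b)})
    k = len(haplotypes)
    index = {h: i for i, h in enumerate(haplotypes)}

    def loglik(freqs: np.ndarray) -> float:
        total = 0.0
        for pairs in pair_lists:
            s = sum(c * freqs[index[a]] * freqs[index[b]] for a, b, c in pairs)
            if s <= 0:
                return -np.inf
            total += np.log(s)
        return total

    starts: list[np.ndarray] = []
    if k <= 4:
        best_f, best_ll = None, -np.inf
        for combo in itertools.combinations(range(grid_points + k - 1), k - 1):
            parts = np.diff((-1, *combo, grid_points + k - 1)) - 1
            freqs = parts / grid_points
            ll = loglik(freqs)
            if ll > best_ll:
                best_f, best_ll = freqs, ll
        starts.append(best_f)
    rng = np.random.default_rng(seed)
    starts.append(np.full(k, 1.0 / k))
    starts.extend(rng.dirichlet(np.ones(k)) for _ in range(n_starts))

    def neg_ll_soft(x: np.ndarray) -> float:
        e = np.exp(x - x.max())
        return -loglik(e / e.sum())

    best_x, best_val = None, np.inf
    for f0 in starts:
        x0 = np.log(np.maximum(f0, 1e-6))
        res = minimize(neg_ll_soft, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 20000})
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    e = np.exp(best_x - best_x.max())
    freqs = e / e.sum()
    return dict(zip(haplotypes, freqs)), float(-best_val)
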