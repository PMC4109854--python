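"""Homotypic cis-regulatory module (CRM) scoring.

Each region is scanned for clusters of binding sites of a *single* PWM with a
two-state generative model: outside a cluster the sequence is emitted by a
0-order background; inside a cluster, motif sites (either strand) alternate
with background gaps whose lengths are geometric with mean ``gap_expectation``.
The region score is the log2 likelihood ratio of the best-scoring cluster
versus pure background, maximised exactly by dynamic programming (Viterbi-style
max over site placements).  A score of 0 with an empty cluster means no
positive-scoring cluster exists.

Scoring model, for a cluster of sites at starts q_1 < ... < q_m (widths W):

    score = sum_j siteLLR(q_j) + sum_{j>=2} [log2 p + g_j * log2(1-p)] - open

where siteLLR is the pseudocounted log-odds of the site against the
background, g_j = q_j - (q_{j-1}+W) is the gap, p = 1/(1+gap_expectation),
and ``open`` is the cluster-opening cost in bits (prior odds of a cluster).
Background-emitted bases cancel in the ratio, so only sites and gap-length
terms appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .pwm import PWM, BASE_INDEX, MIN_SCORING_WIDTH, DEFAULT_PSEUDOCOUNT

_CODE = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

NEG_INF = -1e30


@dataclass
class CrmScoreParams:
    """Parameters of the homotypic cluster model.

    gap_expectation: expected background gap (bp) between sites in a cluster.
    pseudocount: additive count per PWM cell.
    background: 0-order base frequencies (A,C,G,T); ``None`` estimates them
        from the scanned sequence itself (strand-symmetrised).
    cluster_open_bits: log2 prior odds against opening a cluster.
    strands: only ``"both"`` is supported (sites on either strand).
    """

    gap_expectation: float = 35.0
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray | None = None
    cluster_open_bits: float = 4.0
    strands: str = "both"

    def __post_init__(self) -> None:
        if self.gap_expectation <= 0:
            raise ValueError("gap_expectation must be > 0")
        if self.strands != "both":
            raise ValueError("only both-strand scanning is supported")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be 4 frequencies summing to 1")
            self.background = bg

    @property
    def gap_continue_log2(self) -> float:
        p = 1.0 / (1.0 + self.gap_expectation)
        return float(np.log2(1.0 - p))

    @property
    def gap_open_log2(self) -> float:
        p = 1.0 / (1.0 + self.gap_expectation)
        return float(np.log2(p))


@dataclass
class RegionScore:
    """Best homotypic cluster of one PWM in one region."""

    motif_id: str
    gene_id: str
    region_index: int
    species_id: str
    score: float
    best_cluster: tuple[int, int] | None = None
    sites: list[tuple[int, str, float]] = field(default_factory=list)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} (any case) to codes 0..4."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if np.any(codes < 0):
        bad = sorted({sequence[i] for i in np.where(codes < 0)[0]})
        raise ValueError(f"invalid characters in sequence: {bad}")
    return codes.astype(np.int8)


def estimate_background(codes: np.ndarray, symmetrize: bool = True) -> np.ndarray:
    """0-order base frequencies of a coded sequence, +1 pseudocount per base.

    Strand-symmetrised (A=T, C=G averaged) so both-strand scores are invariant
    under reverse complementation of the input.
    """
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float) + 1.0
    freqs = counts / counts.sum()
    if symmetrize:
        at = (freqs[0] + freqs[3]) / 2.0
        cg = (freqs[1] + freqs[2]) / 2.0
        freqs = np.array([at, cg, cg, at])
    return freqs


def _site_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Site log-odds at every start position for one orientation.

    ``lom`` is (W, 4) log2 odds; N bases (code 4) contribute 0.
    """
    W = lom.shape[0]
    n = codes.size - W + 1
    if n <= 0:
        return np.zeros(0)
    lom5 = np.hstack([lom, np.zeros((W, 1))])  # column for N
    scores = np.zeros(n)
    for j in range(W):
        scores += lom5[j, codes[j:j + n]]
    return scores


@njit(cache=True)
def _dp_best_score(site_f, site_r, W, open_cost, gap_open, gap_cont):  # pragma: no cover
    """Max cluster score over all non-overlapping site placements (both strands)."""
    n = site_f.shape[0]
    best = 0.0
    M = NEG_INF  # max over finished sites q of f(q) - end(q)*gap_cont
    fvals = np.empty(n)
    for i in range(n):
        j = i - W
        if j >= 0:
            cand = fvals[j] - (j + W) * gap_cont
            if cand > M:
                M = cand
        s = site_f[i] if site_f[i] >= site_r[i] else site_r[i]
        prev = M + i * gap_cont + gap_open
        base = prev if prev > -open_cost else -open_cost
        f = s + base
        fvals[i] = f
        if f > best:
            best = f
    return best


def _dp_with_traceback(site_f, site_r, W, open_cost, gap_open, gap_cont):
    """Reference DP with parent pointers; returns (score, site index list)."""
    n = site_f.shape[0]
    best, best_i = 0.0, -1
    M, M_arg = NEG_INF, -1
    fvals = np.empty(n)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        j = i - W
        if j >= 0:
            cand = fvals[j] - (j + W) * gap_cont
            if cand > M:
                M, M_arg = cand, j
        s = max(site_f[i], site_r[i])
        prev = M + i * gap_cont + gap_open
        if prev > -open_cost:
            fvals[i] = s + prev
            parent[i] = M_arg
        else:
            fvals[i] = s - open_cost
        if fvals[i] > best:
            best, best_i = fvals[i], i
    chain: list[int] = []
    i = best_i
    while i >= 0:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    return best, chain


def score_homotypic_crm(
    sequence: str,
    pwm: PWM,
    params: CrmScoreParams | None = None,
    *,
    gene_id: str = "",
    region_index: int = 0,
    species_id: str = "",
) -> RegionScore:
    """Score one region for homotypic clusters of one PWM.

    Returns the maximum-scoring cluster (log2 units) with its interval and
    site list; score 0 with an empty cluster when nothing positive exists.
    """
    params = params or CrmScoreParams()
    if pwm.width < MIN_SCORING_WIDTH:
        raise ValueError(f"{pwm.motif_id}: motifs shorter than "
                         f"{MIN_SCORING_WIDTH} bp cannot be scored")
    codes = encode_sequence(sequence)
    empty = RegionScore(pwm.motif_id, gene_id, region_index, species_id, 0.0)
    if codes.size < pwm.width:
        return empty
    bg = (params.background if params.background is not None
          else estimate_background(codes))
    lom_f = pwm.log_odds(bg, params.pseudocount)
    lom_r = pwm.reverse_complement().log_odds(bg, params.pseudocount)
    site_f = _site_scores(codes, lom_f)
    site_r = _site_scores(codes, lom_r)
    score, chain = _dp_with_traceback(
        site_f, site_r, pwm.width, params.cluster_open_bits,
        params.gap_open_log2, params.gap_continue_log2)
    if score <= 0.0 or not chain:
        return empty
    sites = []
    for i in chain:
        strand = "+" if site_f[i] >= site_r[i] else "-"
        sites.append((int(i), strand, float(max(site_f[i], site_r[i]))))
    cluster = (sites[0][0], sites[-1][0] + pwm.width)
    return RegionScore(pwm.motif_id, gene_id, region_index, species_id,
                       float(score), cluster, sites)


# ---------------------------------------------------------------------------
# Bulk scanning (whole region set x PWM collection)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_batch(codes, starts, ends, lom_f5, lom_r5, W,
                open_cost, gap_open, gap_cont, out):  # pragma: no cover
    nreg = starts.shape[0]
    for r in range(nreg):
        s0, e0 = starts[r], ends[r]
        L = e0 - s0
        n = L - W + 1
        if n <= 0:
            out[r] = 0.0
            continue
        best = 0.0
        M = NEG_INF
        fvals = np.empty(n)
        for i in range(n):
            j = i - W
            if j >= 0:
                cand = fvals[j] - (j + W) * gap_cont
                if cand > M:
                    M = cand
            sf = 0.0
            sr = 0.0
            for k in range(W):
                b = codes[s0 + i + k]
                sf += lom_f5[r, k, b]
                sr += lom_r5[r, k, b]
            s = sf if sf >= sr else sr
            prev = M + i * gap_cont + gap_open
            base = prev if prev > -open_cost else -open_cost
            f = s + base
            fvals[i] = f
            if f > best:
                best = f
        out[r] = best if best > 0.0 else 0.0


def scan_sequences(
    sequences: list[str],
    pwms: list[PWM],
    params: CrmScoreParams | None = None,
) -> np.ndarray:
    """Score every sequence with every PWM; returns (n_sequences, n_pwms).

    Equivalent to calling :func:`score_homotypic_crm` pairwise but batched
    through a jit-compiled kernel.
    """
    params = params or CrmScoreParams()
    for pwm in pwms:
        if pwm.width < MIN_SCORING_WIDTH:
            raise ValueError(f"{pwm.motif_id}: motif too short to score")
    coded = [encode_sequence(s) for s in sequences]
    nreg = len(coded)
    lengths = np.array([c.size for c in coded], dtype=np.int64)
    starts = np.zeros(nreg, dtype=np.int64)
    starts[1:] = np.cumsum(lengths)[:-1]
    ends = starts + lengths
    codes = (np.concatenate(coded) if coded else np.zeros(0, dtype=np.int8))
    if params.background is not None:
        bgs = np.tile(params.background, (nreg, 1))
    else:
        bgs = np.array([estimate_background(c) for c in coded])
    log_bg = np.log2(bgs)  # (nreg, 4)

    out = np.zeros((nreg, len(pwms)))
    for m, pwm in enumerate(pwms):
        logp_f = np.log2(pwm.probabilities(params.pseudocount))
        logp_r = logp_f[::-1, ::-1]
        W = pwm.width
        # per-region log-odds with an extra zero column for N bases
        lom_f5 = np.zeros((nreg, W, 5))
        lom_r5 = np.zeros((nreg, W, 5))
        lom_f5[:, :, :4] = logp_f[None, :, :] - log_bg[:, None, :]
        lom_r5[:, :, :4] = logp_r[None, :, :] - log_bg[:, None, :]
        col = np.empty(nreg)
        _scan_batch(codes, starts, ends, lom_f5, lom_r5, W,
                    params.cluster_open_bits, params.gap_open_log2,
                    params.gap_continue_log2, col)
        out[:, m] = col
    return out


def brute_force_best_cluster(
    sequence: str,
    pwm: PWM,
    params: CrmScoreParams | None = None,
    max_sites: int = 3,
) -> float:
    """Independent oracle: exhaustive max over all ordered non-overlapping
    placements of up to ``max_sites`` sites.  Strand choices contribute
    additively and independently per site, so the max over all 2^m strand
    assignments of a placement is exactly the sum of per-site strand maxima.
    Only feasible on short sequences; used to validate the DP.
    """
    from itertools import combinations

    params = params or CrmScoreParams()
    codes = encode_sequence(sequence)
    if codes.size < pwm.width:
        return 0.0
    bg = (params.background if params.background is not None
          else estimate_background(codes))
    site_f = _site_scores(codes, pwm.log_odds(bg, params.pseudocount))
    site_r = _site_scores(
        codes, pwm.reverse_complement().log_odds(bg, params.pseudocount))
    site_m = np.maximum(site_f, site_r)
    n = site_m.size
    W = pwm.width
    gap_open, gap_cont = params.gap_open_log2, params.gap_continue_log2
    best = 0.0
    for m in range(1, max_sites + 1):
        for pos in combinations(range(n), m):
            if any(pos[j + 1] - pos[j] < W for j in range(m - 1)):
                continue
            total = -params.cluster_open_bits + site_m[pos[0]]
            for j in range(1, m):
                gap = pos[j] - (pos[j - 1] + W)
                total += site_m[pos[j]] + gap_open + gap * gap_cont
            if total > best:
                best = total
    return best
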