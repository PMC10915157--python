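"""Two-state haplotype HMM with bidirectional filtering consensus.

A gamete chromosome is a mosaic of the two parental haplotypes (states 0
and 1).  Observed parental genotype calls are noisy versions of the hidden
state.  Decoding runs the *filtering* recursion (running posterior
``P(s_i | o_1..i)``) along the chromosome and again in the reverse
direction; only sites where the two directional MAP states agree keep a
state, the rest are flagged ambiguous.  On a symmetric stationary chain
Viterbi is direction-invariant, so the bidirectional consensus is only
meaningful under the filtering criterion; a Viterbi mode is still provided
as an alternative decoder.

Two transition modes are supported:

* a constant per-step switch probability between adjacent retained sites
  (crossover calling; default 0.2), and
* a distance-scaled switch probability ``P(d) = 1 - exp(-d * 1e-8)`` with
  ``d`` the bp distance between adjacent loci (SV proofreading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HmmParams",
    "distance_switch_prob",
    "forward_filter",
    "bidirectional_states",
    "viterbi_states",
]

#: rate constant of the distance-scaled transition (per bp)
DISTANCE_RATE = 1e-8


@dataclass(frozen=True)
class HmmParams:
    """Parameters of the two-state genotype-error-correcting HMM.

    init
        Initial probability of state 1 (the two haplotypes are a priori
        indistinguishable, hence 0.5).
    emission
        Probability of observing the true hidden state,
        ``P(o=s | s)``; the complement is a genotyping error.
    transition
        Per-step probability of switching state between adjacent retained
        informative sites (constant mode).
    """

    init: float = 0.5
    emission: float = 0.99
    transition: float = 0.2

    def __post_init__(self) -> None:
        for name in ("init", "emission", "transition"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def distance_switch_prob(distances_bp, rate: float = DISTANCE_RATE):
    """Switch probability ``1 - exp(-d * rate)`` for bp distances ``d``."""
    d = np.asarray(distances_bp, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return -np.expm1(-d * rate)


def _as_matrix(obs):
    o = np.asarray(obs, dtype=np.int8)
    squeeze = o.ndim == 1
    if squeeze:
        o = o[None, :]
    if o.ndim != 2:
        raise ValueError("observations must be 1-D or 2-D")
    if o.size and not np.isin(o, (-1, 0, 1)).all():
        raise ValueError("observations must be in {-1 (missing), 0, 1}")
    return o, squeeze


def _switch_vector(switch, m):
    q = np.asarray(switch, dtype=float)
    if q.ndim == 0:
        q = np.full(max(m - 1, 0), float(q))
    if q.shape != (max(m - 1, 0),):
        raise ValueError(f"need {m - 1} switch probabilities, got {q.shape}")
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("switch probabilities must be in [0, 1)")
    return q


def forward_filter(obs, switch, emission: float = 0.99, init: float = 0.5):
    """Filtered posterior ``P(s_i = 1 | o_1..i)`` at every site.

    Parameters
    ----------
    obs
        Observation codes, shape ``(m,)`` or ``(k, m)``; values 0/1, or -1
        for a skipped emission (the transition over the gap still applies —
        used for missing entries on a fixed locus grid).
    switch
        Scalar, or per-gap array of length ``m - 1``, of switch
        probabilities between adjacent sites.
    """
    o, squeeze = _as_matrix(obs)
    k, m = o.shape
    q = _switch_vector(switch, m)
    e = float(emission)
    out = np.empty((k, m), dtype=float)
    p = np.full(k, float(init))
    for j in range(m):
        if j > 0:
            p = p * (1.0 - q[j - 1]) + (1.0 - p) * q[j - 1]
        oj = o[:, j]
        seen = oj >= 0
        if seen.any():
            like1 = np.where(oj == 1, e, 1.0 - e)
            num = p * like1
            den = num + (1.0 - p) * (1.0 - like1)
            p = np.where(seen, num / den, p)
        out[:, j] = p
    return out[0] if squeeze else out


def bidirectional_states(
    obs,
    switch=None,
    params: HmmParams | None = None,
    tie_tol: float = 1e-12,
    return_probs: bool = False,
):
    """Decode hidden states by forward/reverse filtering consensus.

    The forward pass computes the filtering MAP state at each site (argmax
    of ``P(s_i | o_1..i)``); the reverse pass does the same on the reversed
    sequence (argmax of ``P(s_i | o_i..m)``).  Sites where the two passes
    agree keep that state; discordant sites — and exact posterior ties —
    are marked ambiguous.

    Returns ``(states, ambiguous)`` where ``states`` is int8 in {0, 1}
    (value at ambiguous sites is the forward state and must be ignored)
    and ``ambiguous`` is a boolean mask.  With ``return_probs=True`` the
    two filtered posteriors are appended to the return tuple.
    """
    params = params or HmmParams()
    o, squeeze = _as_matrix(obs)
    q = _switch_vector(params.transition if switch is None else switch, o.shape[1])
    pf = forward_filter(o, q, params.emission, params.init)
    pr = forward_filter(o[:, ::-1], q[::-1], params.emission, params.init)[:, ::-1]
    pf2 = np.atleast_2d(pf)
    pr2 = np.atleast_2d(pr)
    sf = pf2 > 0.5
    sr = pr2 > 0.5
    tie = (np.abs(pf2 - 0.5) <= tie_tol) | (np.abs(pr2 - 0.5) <= tie_tol)
    ambiguous = (sf != sr) | tie
    states = sf.astype(np.int8)
    if squeeze:
        states, ambiguous = states[0], ambiguous[0]
        pf, pr = pf2[0], pr2[0]
    if return_probs:
        return states, ambiguous, pf, pr
    return states, ambiguous


def bidirectional_states_ragged(obs_list, params: HmmParams | None = None, tie_tol: float = 1e-12):
    """Batched :func:`bidirectional_states` for sequences of unequal
    length under a constant per-step switch probability.

    Sequences are padded with skipped emissions; because the transition is
    per *retained* adjacent pair, padding beyond a sequence's end does not
    change its filtered posteriors.  Returns a list of
    ``(states, ambiguous)`` pairs, one per input sequence.
    """
    params = params or HmmParams()
    seqs = [np.asarray(o, dtype=np.int8) for o in obs_list]
    if not seqs:
        return []
    lengths = np.array([s.size for s in seqs])
    m = int(lengths.max())
    if m == 0:
        return [(np.empty(0, dtype=np.int8), np.empty(0, dtype=bool)) for _ in seqs]
    fwd = np.full((len(seqs), m), -1, dtype=np.int8)
    rev = np.full((len(seqs), m), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        fwd[i, : s.size] = s
        rev[i, : s.size] = s[::-1]
    pf = forward_filter(fwd, params.transition, params.emission, params.init)
    pr = forward_filter(rev, params.transition, params.emission, params.init)
    out = []
    for i, s in enumerate(seqs):
        n = s.size
        f = pf[i, :n]
        r = pr[i, :n][::-1]
        sf = f > 0.5
        sr = r > 0.5
        tie = (np.abs(f - 0.5) <= tie_tol) | (np.abs(r - 0.5) <= tie_tol)
        out.append((sf.astype(np.int8), (sf != sr) | tie))
    return out


def viterbi_states(obs, switch=None, params: HmmParams | None = None):
    """Most likely joint hidden path (alternative decoder, 1-D input)."""
    params = params or HmmParams()
    o = np.asarray(obs, dtype=np.int8)
    if o.ndim != 1:
        raise ValueError("viterbi_states expects a single sequence")
    m = o.size
    if m == 0:
        return np.empty(0, dtype=np.int8)
    q = _switch_vector(params.transition if switch is None else switch, m)
    loge = np.log([1.0 - params.emission, params.emission])

    def emit(j, s):
        if o[j] < 0:
            return 0.0
        return loge[1] if o[j] == s else loge[0]

    score = np.array(
        [np.log(1.0 - params.init) + emit(0, 0), np.log(params.init) + emit(0, 1)]
    )
    back = np.zeros((m, 2), dtype=np.int8)
    for j in range(1, m):
        lq, ls = np.log(q[j - 1]), np.log(1.0 - q[j - 1])
        new = np.empty(2)
        for s in (0, 1):
            stay = score[s] + ls
            move = score[1 - s] + lq
            if stay >= move:
                new[s] = stay + emit(j, s)
                back[j, s] = s
            else:
                new[s] = move + emit(j, s)
                back[j, s] = 1 - s
        score = new
    path = np.empty(m, dtype=np.int8)
    path[-1] = int(score[1] > score[0])
    for j in range(m - 1, 0, -1):
        path[j - 1] = back[j, path[j]]
    return path
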