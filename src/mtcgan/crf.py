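"""Linear-chain CRF on top of generator label scores.

The generator emits per-position real-valued scores over the tag space
(emissions).  A CRF with learned transition/start/stop parameters is fitted
post hoc on those scores by maximising the sequence log-likelihood with the
emissions held fixed, and decoded with Viterbi.

Tie-breaking is deterministic: among equal-scoring paths the lowest tag
index wins (``argmax`` returns the first maximum), so an exhaustive
enumeration oracle agrees bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CrfParams", "bio_transition_mask", "crf_fit", "viterbi_decode"]

NEG_INF = -1e30


def bio_transition_mask(tags: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of ALLOWED moves under BIO semantics.

    Returns (allowed_transitions (n, n), allowed_start (n,)): I-X may only
    follow B-X or I-X, no path may start with I-X, and a padding tag
    ("<pad>") is unreachable.
    """
    n = len(tags)
    trans = np.ones((n, n), dtype=bool)
    start = np.ones(n, dtype=bool)
    for j, tj in enumerate(tags):
        if tj == "<pad>":
            start[j] = False
            trans[:, j] = False
            continue
        if not tj.startswith("I-"):
            continue
        typ = tj[2:]
        start[j] = False
        for i, ti in enumerate(tags):
            if ti not in (f"B-{typ}", f"I-{typ}"):
                trans[i, j] = False
    return trans, start


@dataclass
class CrfParams:
    transitions: np.ndarray  # (n_tags, n_tags)
    start: np.ndarray  # (n_tags,)
    stop: np.ndarray  # (n_tags,)
    tags: list[str] = field(default_factory=list)
    hard_mask: bool = False

    def __post_init__(self):
        for arr in (self.transitions, self.start, self.stop):
            if not np.isfinite(np.where(arr <= NEG_INF, 0.0, arr)).all():
                raise ValueError("CRF parameters must be finite (or hard-masked)")

    @classmethod
    def zeros(cls, n_tags: int, tags: list[str] | None = None,
              hard_mask: bool = False) -> "CrfParams":
        p = cls(
            transitions=np.zeros((n_tags, n_tags)),
            start=np.zeros(n_tags),
            stop=np.zeros(n_tags),
            tags=list(tags) if tags else [],
            hard_mask=hard_mask,
        )
        if hard_mask:
            p.apply_mask()
        return p

    def apply_mask(self) -> None:
        if not self.tags:
            raise ValueError("hard masking requires the tag list")
        allowed_t, allowed_s = bio_transition_mask(self.tags)
        self.transitions[~allowed_t] = NEG_INF
        self.start[~allowed_s] = NEG_INF


def viterbi_decode(scores: np.ndarray, params: CrfParams) -> list[int]:
    """Maximum-scoring tag path under emissions + transitions.

    scores: (T, n_tags) emission scores.  Path score =
    start[y_0] + sum_t emis[t, y_t] + sum_t trans[y_{t-1}, y_t] + stop[y_T].
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] < 1:
        raise ValueError("scores must be (T >= 1, n_tags)")
    t_len, n = scores.shape
    delta = params.start + scores[0]
    back = np.zeros((t_len, n), dtype=np.intp)
    for t in range(1, t_len):
        cand = delta[:, None] + params.transitions  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max: lowest index wins
        delta = cand[back[t], np.arange(n)] + scores[t]
    delta = delta + params.stop
    path = [int(np.argmax(delta))]
    for t in range(t_len - 1, 0, -1):
        path.append(int(back[t][path[-1]]))
    return path[::-1]


def _pad_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    t_max = max(s.shape[0] for s in seqs)
    n = seqs[0].shape[1]
    emis = np.zeros((len(seqs), t_max, n))
    mask = np.zeros((len(seqs), t_max), dtype=bool)
    for i, s in enumerate(seqs):
        emis[i, : s.shape[0]] = s
        mask[i, : s.shape[0]] = True
    return emis, mask


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m, axis) + np.log(np.exp(x - m).sum(axis=axis))


def crf_fit(
    score_sequences: list[np.ndarray],
    gold_tag_ids: list[np.ndarray],
    n_tags: int,
    tags: list[str] | None = None,
    hard_mask: bool = False,
    iters: int = 80,
    lr: float = 0.5,
    return_history: bool = False,
):
    """Fit transition/start/stop parameters by gradient ascent on the CRF
    log-likelihood with emissions fixed to the supplied generator scores.

    The gradient is observed minus expected sufficient statistics from the
    forward-backward recursions, computed batched over padded sequences.
    """
    if not score_sequences:
        raise ValueError("crf_fit needs at least one sequence")
    if len(score_sequences) != len(gold_tag_ids):
        raise ValueError("scores and gold lengths differ")
    emis, mask = _pad_batch([np.asarray(s, dtype=np.float64) for s in score_sequences])
    b, t_max, n = emis.shape
    if n != n_tags:
        raise ValueError("emission width != n_tags")
    gold = np.zeros((b, t_max), dtype=np.intp)
    for i, g in enumerate(gold_tag_ids):
        if len(g) != score_sequences[i].shape[0]:
            raise ValueError("gold and scores misaligned")
        gold[i, : len(g)] = g
    lengths = mask.sum(axis=1)

    # observed sufficient statistics (fixed)
    obs_trans = np.zeros((n, n))
    obs_start = np.zeros(n)
    obs_stop = np.zeros(n)
    for i in range(b):
        g = gold[i, : lengths[i]]
        obs_start[g[0]] += 1
        obs_stop[g[-1]] += 1
        np.add.at(obs_trans, (g[:-1], g[1:]), 1.0)

    params = CrfParams.zeros(n, tags, hard_mask=hard_mask)
    if hard_mask:
        allowed_t, allowed_s = bio_transition_mask(params.tags)
    m_t = np.zeros((n, n))
    m_s = np.zeros(n)
    m_e = np.zeros(n)
    history: list[float] = []

    for it in range(iters):
        trans, start, stop = params.transitions, params.start, params.stop
        # forward
        alphas = np.full((b, t_max, n), NEG_INF)
        alphas[:, 0] = start[None, :] + emis[:, 0]
        for t in range(1, t_max):
            nxt = _logsumexp(alphas[:, t - 1][:, :, None] + trans[None], axis=1) + emis[:, t]
            alphas[:, t] = np.where(mask[:, t][:, None], nxt, alphas[:, t - 1])
        last = alphas[np.arange(b), lengths - 1]  # (B, n)
        log_z = _logsumexp(last + stop[None], axis=1)  # (B,)
        # gold path score
        gscore = start[gold[:, 0]] + emis[np.arange(b), 0, gold[:, 0]]
        for t in range(1, t_max):
            step = trans[gold[:, t - 1], gold[:, t]] + emis[np.arange(b), t, gold[:, t]]
            gscore = gscore + np.where(mask[:, t], step, 0.0)
        gscore = gscore + stop[gold[np.arange(b), lengths - 1]]
        ll = float((gscore - log_z).sum()) / b
        history.append(ll)

        # backward
        betas = np.full((b, t_max, n), NEG_INF)
        betas[np.arange(b), lengths - 1] = stop[None, :]
        for t in range(t_max - 2, -1, -1):
            nxt = _logsumexp(
                trans[None] + (emis[:, t + 1] + betas[:, t + 1])[:, None, :], axis=2
            )
            active = mask[:, t + 1][:, None]
            betas[:, t] = np.where(active, nxt, betas[:, t])
            # positions at the end of shorter sequences already hold stop

        # expected statistics
        exp_start = np.exp(alphas[:, 0] + betas[:, 0] - log_z[:, None]).sum(axis=0)
        exp_stop = np.exp(last + stop[None] - log_z[:, None]).sum(axis=0)
        exp_trans = np.zeros((n, n))
        for t in range(1, t_max):
            act = mask[:, t]
            if not act.any():
                break
            xi = (
                alphas[:, t - 1][:, :, None]
                + trans[None]
                + (emis[:, t] + betas[:, t])[:, None, :]
                - log_z[:, None, None]
            )
            exp_trans += np.exp(np.where(act[:, None, None], xi, NEG_INF)).sum(axis=0)

        g_t = (obs_trans - exp_trans) / b
        g_s = (obs_start - exp_start) / b
        g_e = (obs_stop - exp_stop) / b
        if hard_mask:
            g_t = np.where(allowed_t, g_t, 0.0)
            g_s = np.where(allowed_s, g_s, 0.0)
        # momentum ascent
        m_t = 0.9 * m_t + g_t
        m_s = 0.9 * m_s + g_s
        m_e = 0.9 * m_e + g_e
        params.transitions = params.transitions + lr * m_t
        params.start = params.start + lr * m_s
        params.stop = params.stop + lr * m_e
        if hard_mask:
            params.apply_mask()

    params.tags = list(tags) if tags else []
    if return_history:
        return params, history
    return params
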