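"""The two decoding branches.

Boundary branch: linear-chain CRF over {O, B, I} with learnable transition
scores (plus virtual start/stop), trained by negative log-likelihood
(path score minus log partition) and decoded with Viterbi.

Type branch: two parallel 1-D CNN banks (kernel widths 2/3/4) — one over
the entity-enhanced encoder states, one over radical embeddings — whose
per-token activations are concatenated, passed through a fully-connected
layer and classified with an angular-margin (A-Softmax / SphereFace)
objective.  The margin-m gold logit uses

    phi(theta) = (-1)^k cos(m theta) - 2k,   theta in [k pi/m, (k+1) pi/m],

blended with plain cos(theta) through the standard lambda anneal so early
training is margin-free.  m = 1 reduces exactly to cosine-softmax
cross-entropy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Parameter, Tensor, concat, no_grad, softmax, where
from .corpus_io import NONE_TYPE

BOUNDARY_LABELS = ["O", "B", "I"]
N_BOUNDARY = len(BOUNDARY_LABELS)
NEG_INF = -1e4  # pseudo minus-infinity for forbidden transitions


# ---------------------------------------------------------------------------
# CRF boundary branch

@dataclass
class CrfParams:
    """Transition matrix over boundary labels plus virtual start/stop rows.

    Index layout: 0..L-1 boundary labels, L = start, L+1 = stop.
    ``forbid_invalid`` adds a constant -1e4 to O->I and start->I.
    """

    trans: Parameter
    forbid_invalid: bool = True

    @staticmethod
    def init(rng: np.random.Generator, forbid_invalid: bool = True) -> "CrfParams":
        L = N_BOUNDARY
        return CrfParams(Parameter(rng.normal(0, 0.02, (L + 2, L + 2)), "crf.trans"),
                         forbid_invalid=forbid_invalid)

    @property
    def start(self) -> int:
        return N_BOUNDARY

    @property
    def stop(self) -> int:
        return N_BOUNDARY + 1

    def constraint_mask(self) -> np.ndarray:
        L = N_BOUNDARY
        mask = np.zeros((L + 2, L + 2))
        if self.forbid_invalid:
            O, I = BOUNDARY_LABELS.index("O"), BOUNDARY_LABELS.index("I")
            mask[O, I] = NEG_INF
            mask[self.start, I] = NEG_INF
        return mask

    def effective(self) -> Tensor:
        return self.trans + Tensor(self.constraint_mask())


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def crf_path_score_batch(emissions: Tensor, trans: Tensor, paths: np.ndarray,
                         lengths: np.ndarray) -> Tensor:
    """Scores of given label paths; emissions (B,T,L), paths (B,T) padded."""
    B, T, L = emissions.shape
    paths = np.asarray(paths, dtype=np.intp)
    lengths = np.asarray(lengths, dtype=np.intp)
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(np.float64)
    onehot = np.zeros((B, T, L))
    np.put_along_axis(onehot, paths[..., None], 1.0, axis=2)
    emis = (emissions * Tensor(onehot * mask[..., None])).sum(axis=(1, 2))
    rows_b = np.arange(B)
    score = emis + trans[(np.full(B, N_BOUNDARY), paths[:, 0])]
    if T > 1:
        pair = trans[(paths[:, :-1], paths[:, 1:])] * Tensor(mask[:, 1:])
        score = score + pair.sum(axis=1)
    last = paths[rows_b, lengths - 1]
    score = score + trans[(last, np.full(B, N_BOUNDARY + 1))]
    return score


def crf_log_partition_batch(emissions: Tensor, trans: Tensor,
                            lengths: np.ndarray) -> Tensor:
    """log sum over all label sequences of exp(path score), per sentence."""
    B, T, L = emissions.shape
    lengths = np.asarray(lengths, dtype=np.intp)
    trans_mat = trans[(slice(0, L), slice(0, L))]
    alpha = trans[(N_BOUNDARY, slice(0, L))].reshape(1, L) \
        + emissions[(slice(None), 0, slice(None))]
    for t in range(1, T):
        scores = alpha.reshape(B, L, 1) + trans_mat.reshape(1, L, L) \
            + emissions[(slice(None), t, slice(None))].reshape(B, 1, L)
        nxt = scores.logsumexp(axis=1)
        active = (t < lengths)[:, None]
        alpha = where(np.broadcast_to(active, (B, L)), nxt, alpha)
    final = alpha + trans[(slice(0, L), N_BOUNDARY + 1)].reshape(1, L)
    return final.logsumexp(axis=1)


def crf_path_score(emissions, crf: CrfParams, path: Sequence[int]) -> Tensor:
    """Score of one path: start + transitions + emissions + stop (scalar)."""
    emissions = _as_tensor(emissions)
    path = np.asarray(path, dtype=np.intp)
    if path.min(initial=0) < 0 or path.max(initial=0) >= emissions.shape[-1]:
        raise ValueError("label index outside emission range")
    T = emissions.shape[0]
    return crf_path_score_batch(emissions.reshape(1, T, -1), crf.effective(),
                                path.reshape(1, T), np.array([T])).reshape(())


def crf_log_partition(emissions, crf: CrfParams) -> Tensor:
    emissions = _as_tensor(emissions)
    T = emissions.shape[0]
    return crf_log_partition_batch(emissions.reshape(1, T, -1), crf.effective(),
                                   np.array([T])).reshape(())


def crf_loss(emissions, crf: CrfParams, path: Sequence[int]) -> Tensor:
    """Negative log-likelihood of the gold path; always >= 0."""
    return crf_log_partition(emissions, crf) - crf_path_score(emissions, crf, path)


def viterbi_decode(emissions: np.ndarray, crf: CrfParams) -> list[int]:
    """Globally best label path; ties resolved toward lower label indices."""
    if isinstance(emissions, Tensor):
        emissions = emissions.data
    emissions = np.asarray(emissions, dtype=np.float64)
    T, L = emissions.shape
    trans = crf.trans.data + crf.constraint_mask()
    trans_mat = trans[:L, :L]
    delta = trans[N_BOUNDARY, :L] + emissions[0]
    back = np.zeros((T, L), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + trans_mat
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(L)] + emissions[t]
    delta = delta + trans[:L, N_BOUNDARY + 1]
    path = [int(np.argmax(delta))]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


def crf_path_log_prob(emissions: np.ndarray, crf: CrfParams,
                      path: Sequence[int]) -> float:
    """log p(path | x) under the CRF, computed without graph building."""
    with no_grad():
        s = crf_path_score(emissions, crf, path).item()
        z = crf_log_partition(emissions, crf).item()
    return s - z


# ---------------------------------------------------------------------------
# Radical CNN + A-Softmax type branch

@dataclass
class TypeHeadParams:
    E_rad: Parameter
    convs: dict            # (branch, width) -> {"W": Parameter, "b": Parameter}
    fc_W: Parameter
    fc_b: Parameter
    cls_W: Parameter       # (n_classes, d_feat); rows kept unit-norm
    widths: tuple
    margin: int

    @staticmethod
    def init(d_model: int, n_radicals: int, n_classes: int,
             rng: np.random.Generator, widths=(2, 3, 4), n_filters: int = 32,
             d_feat: int = 64, margin: int = 4) -> "TypeHeadParams":
        convs = {}
        for branch in ("char", "rad"):
            for w in widths:
                convs[(branch, w)] = {
                    "W": Parameter(rng.normal(0, 0.02, (w * d_model, n_filters)),
                                   f"type.{branch}{w}.W"),
                    "b": Parameter(np.zeros(n_filters), f"type.{branch}{w}.b"),
                }
        d_concat = 2 * len(widths) * n_filters
        cls = rng.normal(0, 0.02, (n_classes, d_feat))
        cls /= np.linalg.norm(cls, axis=1, keepdims=True)
        return TypeHeadParams(
            E_rad=Parameter(rng.normal(0, 0.02, (n_radicals, d_model)), "type.E_rad"),
            convs=convs,
            fc_W=Parameter(rng.normal(0, 0.02, (d_concat, d_feat)), "type.fc_W"),
            fc_b=Parameter(np.zeros(d_feat), "type.fc_b"),
            cls_W=Parameter(cls, "type.cls_W"),
            widths=tuple(widths),
            margin=int(margin),
        )

    def parameters(self) -> list[Parameter]:
        out = [self.E_rad, self.fc_W, self.fc_b, self.cls_W]
        for cw in self.convs.values():
            out.extend(cw.values())
        return out

    def renormalize_classifier(self) -> None:
        """Project classifier rows back to the unit sphere (after updates)."""
        norms = np.linalg.norm(self.cls_W.data, axis=1, keepdims=True)
        self.cls_W.data /= np.maximum(norms, 1e-12)


def conv1d_same(x: Tensor, W: Parameter, b: Parameter, width: int) -> Tensor:
    """Width-w convolution over the time axis with 'same' zero padding."""
    B, T, d = x.shape
    if T < 1:
        raise ValueError("empty sequence")
    left, right = (width - 1) // 2, width // 2
    pieces = []
    if left:
        pieces.append(Tensor(np.zeros((B, left, d))))
    pieces.append(x)
    if right:
        pieces.append(Tensor(np.zeros((B, right, d))))
    xp = concat(pieces, axis=1) if len(pieces) > 1 else x
    windows = concat([xp[(slice(None), slice(i, i + T), slice(None))]
                      for i in range(width)], axis=-1)
    return (windows @ W + b).gelu()


def radical_features(states: Tensor, rad_ids: np.ndarray, params: TypeHeadParams,
                     use_char_branch: bool = True,
                     use_radical_branch: bool = True) -> Tensor:
    """Per-token fused type features (B, T, d_feat).

    Branch A convolves the entity-enhanced encoder states; branch B
    convolves radical embeddings.  A disabled branch contributes zeros of
    the same shape, so ablations are a configuration flag, not a different
    architecture.
    """
    rad_ids = np.atleast_2d(np.asarray(rad_ids, dtype=np.intp))
    rad_emb = params.E_rad[rad_ids]
    feats = []
    for branch, x, active in (("char", states, use_char_branch),
                              ("rad", rad_emb, use_radical_branch)):
        for w in params.widths:
            cw = params.convs[(branch, w)]
            f = conv1d_same(x, cw["W"], cw["b"], w)
            feats.append(f if active else Tensor(np.zeros(f.shape)))
    return concat(feats, axis=-1) @ params.fc_W + params.fc_b


def _chebyshev_cos(cos_t: Tensor, m: int) -> Tensor:
    """cos(m * theta) as a polynomial in cos(theta) (integer m >= 1)."""
    if m == 1:
        return cos_t
    prev, cur = Tensor(np.ones(cos_t.shape)), cos_t
    for _ in range(m - 1):
        prev, cur = cur, cos_t * cur * 2.0 - prev
    return cur


def asoftmax_loss(features: Tensor, labels: np.ndarray, cls_W: Parameter,
                  m: int = 1, lam: float = 0.0) -> Tensor:
    """Angular-margin softmax loss, averaged over samples.

    The gold-class logit is ||x|| * phi(theta_y) with the SphereFace
    piecewise phi; other classes keep ||x|| * cos(theta_j).  ``lam`` blends
    the gold logit with the margin-free cos(theta_y) as
    (lam * cos + phi) / (1 + lam) (annealed from large lam during
    training).  With m = 1, phi == cos and the blend is exact cosine
    softmax for any lam.
    """
    if m < 1 or int(m) != m:
        raise ValueError("margin m must be a positive integer")
    labels = np.asarray(labels, dtype=np.intp)
    N = features.shape[0]
    wn = cls_W * (1.0 / ((cls_W * cls_W).sum(axis=1, keepdims=True) + 1e-12).sqrt())
    xnorm = ((features * features).sum(axis=1, keepdims=True) + 1e-12).sqrt()  # (N,1)
    cos = ((features @ wn.swapaxes(0, 1)) / xnorm).clip(-1.0 + 1e-7, 1.0 - 1e-7)
    rows = np.arange(N)
    cos_y = cos[(rows, labels)]                                   # (N,)
    if m == 1:
        f_y = cos_y
    else:
        cos_my = _chebyshev_cos(cos_y, m)
        theta = np.arccos(np.clip(cos_y.data, -1.0, 1.0))
        k = np.minimum(np.floor(m * theta / np.pi), m - 1)
        phi = cos_my * Tensor((-1.0) ** k) - Tensor(2.0 * k)
        f_y = (cos_y * lam + phi) * (1.0 / (1.0 + lam))
    logits = cos * xnorm
    onehot = np.zeros((N, len(cls_W.data)))
    onehot[rows, labels] = 1.0
    adjust = (f_y - cos_y) * xnorm.reshape(N)
    logits = logits + Tensor(onehot) * adjust.reshape(N, 1)
    gold = (logits * Tensor(onehot)).sum(axis=1)
    return (logits.logsumexp(axis=1) - gold).mean()


def type_probabilities(features: Tensor, cls_W: Parameter) -> np.ndarray:
    """Inference-time class probabilities softmax(||x|| cos theta_j)."""
    with no_grad():
        wn = cls_W * (1.0 / ((cls_W * cls_W).sum(axis=1, keepdims=True) + 1e-12).sqrt())
        logits = features @ wn.swapaxes(0, 1)
        return softmax(logits, axis=-1).data


# ---------------------------------------------------------------------------
# Span/type recombination

def resolve_span_type(token_types: Sequence[str],
                      type_scores=None, start: int = 0) -> str:
    """Type for one B..I span from per-token type votes.

    Majority vote over non-NONE per-token types; ties resolved by highest
    mean class probability over the span (when ``type_scores`` =
    (probs array (T, C), class names) is available, else lexicographically);
    an all-NONE span takes the highest mean non-NONE probability.
    """
    votes = Counter(t for t in token_types if t != NONE_TYPE)
    span = slice(start, start + len(token_types))

    def mean_prob(name: str) -> float:
        if type_scores is None:
            return 0.0
        probs, names = type_scores
        return float(probs[span, names.index(name)].mean())

    if votes:
        top = max(votes.values())
        cands = sorted(t for t, c in votes.items() if c == top)
        if len(cands) == 1:
            return cands[0]
        return max(cands, key=lambda t: (mean_prob(t), ), default=cands[0]) \
            if type_scores is not None else cands[0]
    if type_scores is not None:
        probs, names = type_scores
        cands = sorted(n for n in names if n != NONE_TYPE)
        if cands:
            return max(cands, key=mean_prob)
    return NONE_TYPE
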