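"""The four CLCGAN loss terms and their weighted combination.

Terms (all natural-log, all reduced as means over pixels/patches/batch):

* contrastive (patch NCE): -log[ sim(f, f+) / (sim(f, f+) + sum_i sim(f, f-_i)) ]
  with sim(u, v) = exp(cos(u, v) / tau), applied symmetrically for both
  generator directions and averaged;
* adversarial: classic cross-entropy patch-GAN value; the generator update
  uses the non-saturating form by default (least-squares behind a flag);
* cycle consistency: per-pixel L1 of both domain round trips;
* frequency: mean over frequency bins of the squared modulus of the
  unnormalised 2-D DFT of the cycle residual (equals H*W times the pixel
  MSE by Parseval's theorem -- the transform is still genuinely evaluated).

Default weights: lambda = (2, 1, 1, 0.01) for (contrastive, cycle,
adversarial, frequency) and temperature tau = 0.07.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_contrastive: float = 2.0
    lambda_cycle: float = 1.0
    lambda_adversarial: float = 1.0
    lambda_frequency: float = 0.01
    tau: float = 0.07

    def __post_init__(self):
        for name in ("lambda_contrastive", "lambda_cycle",
                     "lambda_adversarial", "lambda_frequency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class LossReport:
    l_cont: float
    l_cyc: float
    l_adv: float
    l_freq: float
    total: float

    def __post_init__(self):
        for name in ("l_cont", "l_cyc", "l_adv", "l_freq", "total"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite loss term {name}")


@dataclass(frozen=True)
class ContrastiveBatch:
    """One query with its positive and k negatives (same embedding dim)."""

    query: np.ndarray
    positive: np.ndarray
    negatives: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.query, dtype=np.float64)
        p = np.asarray(self.positive, dtype=np.float64)
        n = np.atleast_2d(np.asarray(self.negatives, dtype=np.float64))
        if q.shape != p.shape or n.shape[1] != q.shape[0]:
            raise ValueError("embedding dimensions disagree")
        if n.shape[0] < 1:
            raise ValueError("at least one negative required")
        object.__setattr__(self, "query", q)
        object.__setattr__(self, "positive", p)
        object.__setattr__(self, "negatives", n)


# ---------------------------------------------------------------------------
# closed-form (NumPy) reference implementations
# ---------------------------------------------------------------------------

def similarity(u, v, tau: float = 0.07) -> float:
    """exp(cos(u, v) / tau): temperature-scaled cosine similarity."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("similarity undefined for a zero vector")
    return float(np.exp(np.dot(u, v) / (nu * nv * tau)))


def contrastive_loss(batch: ContrastiveBatch, tau: float = 0.07) -> float:
    """-log of the positive's share of total similarity (one query)."""
    # log-sum-exp stabilised; exactly the printed ratio otherwise
    cos = lambda a, b: np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    logits = np.array([cos(batch.query, batch.positive) / tau]
                      + [cos(batch.query, n) / tau for n in batch.negatives])
    m = logits.max()
    return float(np.log(np.sum(np.exp(logits - m))) + m - logits[0])


def adversarial_loss(d_real, d_fake) -> float:
    """The two-term cross-entropy value E[log D(real)] + E[log(1 - D(fake))].

    Scores are probabilities in (0, 1) (sigmoid already applied), averaged
    over the patch map.  The discriminator drives this toward 0 (its
    supremum); logs are clamped for numerical safety.
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _LOG_EPS, 1 - _LOG_EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _LOG_EPS, 1 - _LOG_EPS)
    return float(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df)))


def cycle_loss(n_batch, s_batch, G_SN, G_NS) -> float:
    """Mean-per-pixel L1 of both round trips N->S->N and S->N->S."""
    n = _as_nchw(n_batch)
    s = _as_nchw(s_batch)
    rec_n = _apply(G_SN, _apply(G_NS, n))
    rec_s = _apply(G_NS, _apply(G_SN, s))
    if rec_n.shape != n.shape or rec_s.shape != s.shape:
        raise ValueError("generator changed the image shape")
    return float(np.mean(np.abs(rec_n - n)) + np.mean(np.abs(rec_s - s)))


def frequency_loss(n_batch, s_batch, G_SN, G_NS) -> float:
    """Mean squared DFT modulus of the cycle residuals, both directions."""
    n = _as_nchw(n_batch)
    s = _as_nchw(s_batch)
    res_n = _apply(G_SN, _apply(G_NS, n)) - n
    res_s = _apply(G_NS, _apply(G_SN, s)) - s
    val = 0.0
    for res in (res_n, res_s):
        f = np.fft.fft2(res, axes=(-2, -1))
        val += float(np.mean(np.abs(f) ** 2))
    return val


def total_loss(l_cont: float, l_cyc: float, l_adv: float, l_freq: float,
               weights: LossWeights = LossWeights()) -> LossReport:
    """Weighted sum lambda1*cont + lambda2*cyc + lambda3*adv + lambda4*freq."""
    for name, v in (("contrastive", l_cont), ("cycle", l_cyc),
                    ("adversarial", l_adv), ("frequency", l_freq)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name} loss term")
    tot = (weights.lambda_contrastive * l_cont + weights.lambda_cycle * l_cyc
           + weights.lambda_adversarial * l_adv + weights.lambda_frequency * l_freq)
    return LossReport(l_cont=float(l_cont), l_cyc=float(l_cyc),
                      l_adv=float(l_adv), l_freq=float(l_freq), total=float(tot))


def _as_nchw(x) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    return x


def _apply(g, x: np.ndarray) -> np.ndarray:
    """Apply a generator Module or a plain array->array callable."""
    if hasattr(g, "forward"):
        return g.forward(Tensor(x)).data
    y = g(x)
    return y.data if isinstance(y, Tensor) else np.asarray(y, dtype=x.dtype)


# ---------------------------------------------------------------------------
# differentiable (autodiff) forms used by the training step
# ---------------------------------------------------------------------------

def patch_nce_loss(queries: Tensor, keys: Tensor, tau: float = 0.07) -> Tensor:
    """PatchNCE over P sampled locations: positives on the diagonal.

    ``queries`` and ``keys`` are (N, P, D) unit-norm embeddings at identical
    spatial locations on the two sides; each query's positive is its own
    location's key and its negatives are the other P-1 keys (k = P - 1).
    """
    n, p, d = queries.shape
    if p < 2:
        raise ValueError("need at least 2 locations (1 positive + >=1 negative)")
    logits = T.matmul(queries, T.transpose(keys, (0, 2, 1))) * (1.0 / tau)  # N,P,P
    m = float(logits.data.max())  # detached max for stability
    shifted = logits - m
    lse = T.log(T.sum_(T.exp(shifted), axis=-1)) + m                         # N,P
    diag = T.sum_(mul_diag_mask(logits), axis=-1)                            # N,P
    return mean_all(lse - diag)


def mul_diag_mask(x: Tensor) -> Tensor:
    p = x.shape[-1]
    eye = np.eye(p, dtype=x.data.dtype)
    return x * Tensor(eye)


def mean_all(x: Tensor) -> Tensor:
    return T.mean(x)


def generator_adversarial_loss(d_fake_logits: Tensor, mode: str = "nonsaturating") -> Tensor:
    """Generator objective: drive D(fake) toward 1."""
    if mode == "nonsaturating":
        return T.mean(T.logsigmoid(d_fake_logits)) * -1.0
    if mode == "lsgan":
        return T.mean((T.sigmoid(d_fake_logits) - 1.0) ** 2.0)
    raise ValueError(f"unknown adversarial mode {mode!r}")


def discriminator_adversarial_loss(d_real_logits: Tensor, d_fake_logits: Tensor,
                                   mode: str = "nonsaturating") -> Tensor:
    """Discriminator objective: real toward 1, fake toward 0 (= -value of
    the two-term cross-entropy form)."""
    if mode == "nonsaturating":
        return (T.mean(T.logsigmoid(d_real_logits))
                + T.mean(T.logsigmoid(d_fake_logits * -1.0))) * -1.0
    if mode == "lsgan":
        return (T.mean((T.sigmoid(d_real_logits) - 1.0) ** 2.0)
                + T.mean(T.sigmoid(d_fake_logits) ** 2.0)) * 0.5
    raise ValueError(f"unknown adversarial mode {mode!r}")


def cycle_loss_t(rec: Tensor, orig: Tensor) -> Tensor:
    if rec.shape != orig.shape:
        raise ValueError("shape mismatch in cycle residual")
    return T.mean(T.abs_(rec - orig))


def frequency_loss_t(rec: Tensor, orig: Tensor) -> Tensor:
    if rec.shape != orig.shape:
        raise ValueError("shape mismatch in cycle residual")
    return T.fft_power_mean(rec - orig)
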