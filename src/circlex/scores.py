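"""Reference-based tissue scores built from non-negative matrix factorization.

Both the pluripotency score and the neurality score use the same
construction: (1) NMF with k components (default 8) on a labeled
reference cohort, (2) ranking of the components by the AUROC of their
mixing weights for the target class, (3) a ridge-regularized logistic
model over the component weights with the coefficients constrained to be
non-negative (margin-maximizing in the small-ridge limit for separable
data), and (4) scoring of new samples by projecting their profile onto
the basis with non-negative least squares and applying the logistic
linear predictor. Scores are reported on the logit scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CirclexError, ConfigError


# ---------------------------------------------------------------------------
# NMF (multiplicative updates, deterministic SVD-based initialization)

_EPS = 1e-12


def _nndsvd_init(V: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization; zeros filled with the data mean."""
    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    n, m = V.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, min(k, len(s))):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_p = np.linalg.norm(up) * np.linalg.norm(vp)
        n_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if n_p >= n_n:
            sigma = s[j] * n_p
            uu = up / (np.linalg.norm(up) + _EPS)
            vv = vp / (np.linalg.norm(vp) + _EPS)
        else:
            sigma = s[j] * n_n
            uu = un / (np.linalg.norm(un) + _EPS)
            vv = vn / (np.linalg.norm(vn) + _EPS)
        W[:, j] = np.sqrt(sigma) * uu
        H[j, :] = np.sqrt(sigma) * vv
    mean = V.mean()
    rng = np.random.default_rng(seed)
    W[W <= 0] = mean * (0.5 + 0.5 * rng.random(int((W <= 0).sum())))
    H[H <= 0] = mean * (0.5 + 0.5 * rng.random(int((H <= 0).sum())))
    return W, H


def fit_nmf(
    V: np.ndarray | pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Frobenius NMF via multiplicative updates; returns (W, H, objectives).

    The objective ||V - WH||_F^2 is non-increasing under the updates; the
    recorded per-iteration sequence makes that auditable. Iteration stops
    at relative improvement < ``tol`` or ``max_iter``.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ConfigError("NMF input must be non-negative")
    if not 1 <= k <= min(V.shape):
        raise ConfigError(f"k={k} must lie in [1, min(V.shape)={min(V.shape)}]")
    W, H = _nndsvd_init(V, k, seed)
    obj = [float(np.linalg.norm(V - W @ H) ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj.append(float(np.linalg.norm(V - W @ H) ** 2))
        if obj[-2] - obj[-1] < tol * max(obj[-2], _EPS):
            break
    return W, H, obj


# ---------------------------------------------------------------------------
# component ranking and the constrained logistic head


def auroc(scores, is_target) -> float:
    """AUROC of ``scores`` for the target class, midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ConfigError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def rank_components(H: np.ndarray, class_labels, target_class) -> tuple[np.ndarray, np.ndarray]:
    """AUROC of each H row for target-vs-rest; components sorted descending."""
    labels = pd.Series(class_labels)
    y = (labels == target_class).to_numpy()
    if y.all() or not y.any():
        raise ConfigError("both classes must be present")
    aurocs = np.array([auroc(H[j], y) for j in range(H.shape[0])])
    ranking = np.argsort(-aurocs, kind="mergesort")
    return aurocs, ranking


def fit_nonneg_logistic(
    H: np.ndarray,
    class_labels,
    target_class,
    ridge: float = 1e-3,
    max_iter: int = 200_000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """Ridge logistic regression with non-negative weights.

    Minimizes mean log-loss + (ridge/2)||w||^2 subject to w >= 0 (free,
    unpenalized intercept) by projected gradient descent from the
    deterministic start w = 0, b = log-odds. The objective is strictly
    convex, so the constrained optimum is unique.
    """
    Z = np.asarray(H, dtype=float).T  # samples x k
    labels = pd.Series(class_labels)
    y = (labels == target_class).to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ConfigError("both classes must be present")
    n, k = Z.shape
    if ridge <= 0:
        raise ConfigError("ridge must be > 0")

    Zb = np.column_stack([Z, np.ones(n)])
    # Lipschitz bound for the logistic gradient: 0.25 * lambda_max(Z'Z)/n + ridge
    lam = np.linalg.eigvalsh(Zb.T @ Zb / n).max()
    step = 1.0 / (0.25 * lam + ridge)

    pbar = y.mean()
    w = np.zeros(k)
    b = float(np.log(pbar / (1 - pbar)))

    def grad(w, b):
        eta = Z @ w + b
        mu = 1.0 / (1.0 + np.exp(-eta))
        gw = Z.T @ (mu - y) / n + ridge * w
        gb = float((mu - y).mean())
        return gw, gb

    for it in range(max_iter):
        gw, gb = grad(w, b)
        w_new = np.clip(w - step * gw, 0.0, None)
        b_new = b - step * gb
        move = np.sqrt(np.sum((w_new - w) ** 2) + (b_new - b) ** 2)
        w, b = w_new, b_new
        if move < tol * step:
            return w, b
    raise CirclexError(
        f"non-negative logistic did not converge in {max_iter} iterations "
        f"(last move {move:.3e}, step {step:.3e})"
    )


def project_sample(sample_profile: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Non-negative least squares weights h minimizing ||x - W h||^2."""
    x = np.asarray(sample_profile, dtype=float)
    if x.shape[0] != W.shape[0]:
        raise ConfigError(f"profile length {x.shape[0]} != basis rows {W.shape[0]}")
    h, _ = optimize.nnls(W, x)
    return h


# ---------------------------------------------------------------------------
# model object


@dataclass
class TissueScoreModel:
    """NMF basis plus a non-negative logistic head for one target class."""

    W: np.ndarray
    gene_ids: list[str]
    shift: float
    component_auroc: np.ndarray
    ranking: np.ndarray
    weights: np.ndarray
    intercept: float
    target_class: str
    k: int
    seed: int
    objective: list[float] = field(default_factory=list)

    def score(self, samples: pd.DataFrame) -> pd.Series:
        """Score samples (genes x samples) on the logit scale.

        Genes are matched by id; basis genes absent from the input raise
        a warning and are dropped from the projection (intersection
        policy). The reference non-negativity shift is reapplied and the
        result floored at zero.
        """
        idx = pd.Index(self.gene_ids)
        common = idx.intersection(samples.index)
        if len(common) == 0:
            raise ConfigError("no overlap between model genes and sample genes")
        if len(common) < len(idx):
            missing = idx.difference(samples.index)
            warnings.warn(
                f"{len(missing)} basis genes missing from input (e.g. {list(missing)[:3]}); "
                "projecting on the intersection"
            )
        pos = idx.get_indexer(common)
        Wsub = self.W[pos, :]
        X = np.clip(samples.loc[common].to_numpy(float) - self.shift, 0.0, None)
        out = np.empty(X.shape[1])
        for i in range(X.shape[1]):
            h = project_sample(X[:, i], Wsub)
            out[i] = float(self.weights @ h + self.intercept)
        return pd.Series(out, index=samples.columns, name=f"{self.target_class}_score")

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "shift": self.shift,
            "component_auroc": self.component_auroc.tolist(),
            "ranking": self.ranking.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "target_class": self.target_class,
            "k": self.k,
            "seed": self.seed,
        }
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(self.W, index=self.gene_ids).to_csv(outdir / "basis.tsv", sep="\t")

    @classmethod
    def load(cls, outdir: str | Path) -> "TissueScoreModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model.json").read_text())
        basis = pd.read_csv(outdir / "basis.tsv", sep="\t", index_col=0)
        return cls(
            W=basis.to_numpy(float),
            gene_ids=[str(g) for g in basis.index],
            shift=float(meta["shift"]),
            component_auroc=np.asarray(meta["component_auroc"], float),
            ranking=np.asarray(meta["ranking"], int),
            weights=np.asarray(meta["weights"], float),
            intercept=float(meta["intercept"]),
            target_class=str(meta["target_class"]),
            k=int(meta["k"]),
            seed=int(meta["seed"]),
        )


def train_tissue_score_model(
    reference: pd.DataFrame,
    class_labels,
    target_class: str,
    k: int = 8,
    seed: int = 0,
    exclude_labels: tuple = (),
    max_iter: int = 500,
    tol: float = 1e-4,
    ridge: float = 1e-3,
    _nmf_cache: tuple | None = None,
) -> TissueScoreModel:
    """Train one tissue score on a labeled reference (genes x samples).

    The input is shifted by its global minimum to make it non-negative
    (the shift is stored and reapplied at projection time). Samples whose
    label is in ``exclude_labels`` are dropped before factorization.
    ``_nmf_cache`` lets two heads (pluripotency, neurality) share one
    factorization of the same reference.
    """
    labels = pd.Series(class_labels, index=reference.columns)
    keep = ~labels.isin(exclude_labels)
    ref = reference.loc[:, keep.to_numpy()]
    labels = labels[keep.to_numpy()]
    if target_class not in set(labels):
        raise ConfigError(f"target class '{target_class}' absent from labels")

    shift = float(ref.to_numpy().min())
    V = ref.to_numpy(float) - shift
    if _nmf_cache is not None:
        W, H, obj = _nmf_cache
    else:
        W, H, obj = fit_nmf(V, k=k, seed=seed, max_iter=max_iter, tol=tol)
    aurocs, ranking = rank_components(H, labels, target_class)
    w, b = fit_nonneg_logistic(H, labels, target_class, ridge=ridge)
    return TissueScoreModel(
        W=W,
        gene_ids=[str(g) for g in ref.index],
        shift=shift,
        component_auroc=aurocs,
        ranking=ranking,
        weights=w,
        intercept=b,
        target_class=str(target_class),
        k=k,
        seed=seed,
        objective=obj,
    )


def score_samples(
    samples: pd.DataFrame,
    model_pluri: TissueScoreModel,
    model_neural: TissueScoreModel,
) -> pd.DataFrame:
    """Pluripotency and neurality scores per sample, input order preserved."""
    return pd.DataFrame(
        {
            "pluripotency_score": model_pluri.score(samples),
            "neurality_score": model_neural.score(samples),
        }
    )
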