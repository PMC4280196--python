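"""Random-frog wavelength selection.

Random frog is a reversible-jump-MCMC-flavoured search over variable
subsets with an embedded PLS submodel.  A chain of ``T`` iterations starts
from a random subset of ``Q`` variables; at each step a candidate subset
of a perturbed size Q* ~ round(N(Q_t, theta * Q_t)) is proposed, its
cross-validated PLS error is compared with the incumbent's, and the
candidate is accepted outright when it is no worse, or with probability
``eta * err_incumbent / err_candidate`` (< eta) when it is worse.  A
variable's *selection probability* (SP) is the fraction of iterations in
which it sat in the retained subset; SPs are averaged over ``n_runs``
independent chains and ranked to pick the informative wavelengths.

Candidate construction (growing and shrinking moves):

* Q* = Q_t: the candidate is the incumbent subset itself.
* Q* < Q_t: fit the PLS submodel on the incumbent and keep the Q*
  variables with the largest absolute regression coefficients.
* Q* > Q_t: draw ``omega * (Q* - Q_t)`` fresh variables uniformly from the
  complement, pool them with the incumbent, fit the submodel on the pool,
  and keep the Q* largest-|coefficient| variables.

The submodel error is k-fold (default 5-fold, contiguous, deterministic)
cross-validated RMSE with at most ``submodel_max_lvs`` latent variables.
Each run derives its seed from the master seed, so a fixed seed gives
bit-identical SP vectors across invocations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .hypercube_io import SpectraTable

__all__ = ["FrogConfig", "FrogResult", "random_frog", "rank_wavelengths"]


@dataclass
class FrogConfig:
    """Chain parameters.  Defaults are the full-scale study settings."""

    T: int = 10_000            # iterations per run
    Q: int = 50                # initial subset size
    theta: float = 0.3         # sd of the subset-size proposal = theta * Q_t
    omega: int = 3             # candidate-pool multiplier for growing moves
    eta: float = 0.1           # upper bound of the acceptance probability
    n_runs: int = 50           # independent chains averaged into the SP
    rng_seed: int = 0
    submodel_max_lvs: int = 10
    cv_folds: int = 5

    def validate(self, p: int | None = None) -> "FrogConfig":
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if p is not None and self.Q > p:
            warnings.warn(
                f"initial subset size Q={self.Q} exceeds the number of "
                f"variables p={p}; clipping Q to p", stacklevel=2)
            return replace(self, Q=p)
        return self


@dataclass
class FrogResult:
    """Averaged selection probabilities and per-run traces."""

    selection_probability: np.ndarray   # (p,) mean SP over runs
    run_sp: np.ndarray                  # (n_runs, p)
    wavelengths: np.ndarray             # (p,) nm labels
    mean_subset_size: np.ndarray        # (n_runs,) time-averaged |subset|
    n_rejected_nonfinite: int
    config: FrogConfig

    @property
    def ranking(self) -> np.ndarray:
        """Variable indices sorted by SP descending, ties by lower
        wavelength."""
        # lexsort: last key is primary
        return np.lexsort((self.wavelengths, -self.selection_probability))

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": [float(w) for w in self.wavelengths],
            "selection_probability": [float(s) for s in self.selection_probability],
            "config": {k: (v if isinstance(v, (int, float)) else v)
                       for k, v in self.config.__dict__.items()},
        }


# ---------------------------------------------------------------------------
# Submodel plumbing (PLS1 CV error on a variable subset)
# ---------------------------------------------------------------------------

def _cv_folds(n: int, k: int) -> list[tuple[np.ndarray, slice]]:
    bounds = np.linspace(0, n, k + 1).astype(int)
    return [(np.r_[0:lo, hi:n], slice(lo, hi))
            for lo, hi in zip(bounds[:-1], bounds[1:])]


def _submodel_error(X: np.ndarray, y: np.ndarray, cols: np.ndarray,
                    folds, max_lvs: int) -> float:
    """k-fold CV RMSE of the PLS1 submodel restricted to ``cols``."""
    from .regression import pls1_fit_predict
    Xs = X[:, cols]
    n = len(y)
    sse = 0.0
    for tr, te in folds:
        a = min(len(cols), max_lvs, len(tr) - 1)
        pred = pls1_fit_predict(Xs[tr], y[tr], Xs[te], a)
        sse += float(((pred - y[te]) ** 2).sum())
    return float(np.sqrt(sse / n))


def _submodel_coefficients(X: np.ndarray, y: np.ndarray, cols: np.ndarray,
                           max_lvs: int) -> np.ndarray:
    from .regression import _nipals_pls1, _pls1_coefficients
    a = min(len(cols), max_lvs, X.shape[0] - 1)
    _, _, W, P, q, _ = _nipals_pls1(X[:, cols], y, a)
    return _pls1_coefficients(W, P, q)


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

def _one_run(X: np.ndarray, y: np.ndarray, cfg: FrogConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, float, int]:
    n, p = X.shape
    folds = _cv_folds(n, cfg.cv_folds)
    counts = np.zeros(p)
    rejected_nonfinite = 0

    current = np.sort(rng.choice(p, size=cfg.Q, replace=False))
    err_current = _submodel_error(X, y, current, folds, cfg.submodel_max_lvs)
    size_sum = 0

    for _ in range(cfg.T):
        q_t = len(current)
        q_star = int(np.clip(round(rng.normal(q_t, cfg.theta * q_t)), 1, p))

        if q_star == q_t:
            candidate = current
            err_candidate = err_current
        else:
            if q_star < q_t:
                pool = current
            else:
                n_new = min(cfg.omega * (q_star - q_t), p - q_t)
                complement = np.setdiff1d(np.arange(p), current,
                                          assume_unique=True)
                extra = rng.choice(complement, size=n_new, replace=False)
                pool = np.sort(np.concatenate([current, extra]))
            coef = _submodel_coefficients(X, y, pool, cfg.submodel_max_lvs)
            # keep the q_star largest |coefficients|; ties to lower index
            order = np.argsort(-np.abs(coef), kind="stable")[:q_star]
            candidate = np.sort(pool[order])
            err_candidate = _submodel_error(X, y, candidate, folds,
                                            cfg.submodel_max_lvs)

        if not np.isfinite(err_candidate):
            rejected_nonfinite += 1
        elif err_candidate <= err_current:
            current, err_current = candidate, err_candidate
        elif rng.uniform() < cfg.eta * err_current / err_candidate:
            current, err_current = candidate, err_candidate

        counts[current] += 1
        size_sum += len(current)

    return counts / cfg.T, size_sum / cfg.T, rejected_nonfinite


def random_frog(table: SpectraTable, config: FrogConfig) -> FrogResult:
    """Run ``config.n_runs`` independent frog chains on a spectra table and
    average the per-variable selection probabilities."""
    X, y = table.X, table.y
    n, p = X.shape
    if p < 2 and p != 1:
        raise ValueError("need at least one variable")
    cfg = config.validate(p)
    if n < cfg.cv_folds:
        raise ValueError(
            f"need at least cv_folds={cfg.cv_folds} samples, got {n}")

    if p == 1:
        # degenerate chain: the only subset is the single variable
        sp = np.ones((cfg.n_runs, 1))
        return FrogResult(
            selection_probability=np.ones(1), run_sp=sp,
            wavelengths=table.wavelengths.copy(),
            mean_subset_size=np.ones(cfg.n_runs),
            n_rejected_nonfinite=0, config=cfg)

    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_runs)
    run_sp = np.empty((cfg.n_runs, p))
    mean_sizes = np.empty(cfg.n_runs)
    n_bad = 0
    for r, ss in enumerate(seeds):
        sp, msize, bad = _one_run(X, y, cfg, np.random.default_rng(ss))
        run_sp[r] = sp
        mean_sizes[r] = msize
        n_bad += bad

    return FrogResult(
        selection_probability=run_sp.mean(axis=0), run_sp=run_sp,
        wavelengths=table.wavelengths.copy(), mean_subset_size=mean_sizes,
        n_rejected_nonfinite=n_bad, config=cfg)


def rank_wavelengths(result: FrogResult, k: int) -> np.ndarray:
    """Top-``k`` wavelengths (nm) by selection probability, descending;
    ties break toward the lower wavelength."""
    p = len(result.selection_probability)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return result.wavelengths[result.ranking[:k]]
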