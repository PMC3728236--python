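"""Partial Credit Model estimation and Rasch fit / reliability statistics.

The Partial Credit Model (PCM) extends the dichotomous Rasch model to
ordered polytomous items. For person n with latent severity theta and item
i with step difficulties delta_i1..delta_im, the probability of category x is

    P(X = x) = exp( sum_{j<=x} (theta - delta_ij) ) /
               sum_{h=0}^{m} exp( sum_{j<=h} (theta - delta_ij) )

with the empty sum for x = 0 equal to 0. Estimation is joint maximum
likelihood (JMLE): alternating Newton-Raphson updates of person measures and
item steps, the native reporting family for the mean-square infit/outfit and
person/item separation statistics computed here.

Usage follows the model/results convention::

    model = PartialCreditModel(responses)
    fit = model.fit()
    fit.summary()
    fit.fit_statistics()
    fit.separation_reliability()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ItemSpec, ResponseMatrix, RunConfig, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "category_probabilities",
    "expected_score_and_variance",
    "PartialCreditModel",
    "PCMResults",
    "ItemFitStats",
    "ScaleStats",
    "fit_pcm",
    "fit_statistics",
    "separation_reliability",
    "reliability_from_separation",
    "separation_from_reliability",
    "fit_by_subscale",
]


def _cumulative_logits(theta: float | np.ndarray, steps: np.ndarray) -> np.ndarray:
    """psi_h = sum_{j<=h}(theta - delta_j), h = 0..m; vectorised over theta."""
    steps = np.asarray(steps, dtype=float)
    theta = np.asarray(theta, dtype=float)
    m = steps.shape[0]
    cum = np.concatenate([[0.0], np.cumsum(steps)])  # (m+1,)
    h = np.arange(m + 1)
    return np.multiply.outer(theta, h) - cum  # (..., m+1)


def category_probabilities(theta, steps) -> np.ndarray:
    """PCM category probabilities P(X = 0..m) at severity ``theta``.

    Numerically stable (log-sum-exp shifted) for |theta - delta| up to
    several hundred logits. ``theta`` may be scalar or an array; the
    category axis is last.
    """
    steps = np.asarray(steps, dtype=float)
    if not np.all(np.isfinite(steps)):
        raise ValidationError("non-finite step difficulties")
    psi = _cumulative_logits(theta, steps)
    psi = psi - psi.max(axis=-1, keepdims=True)
    p = np.exp(psi)
    p /= p.sum(axis=-1, keepdims=True)
    return p if np.ndim(theta) else p.reshape(-1)


def expected_score_and_variance(theta, steps) -> tuple:
    """Model-expected category E and category variance W at ``theta``."""
    p = category_probabilities(theta, steps)
    cats = np.arange(p.shape[-1], dtype=float)
    e = (p * cats).sum(axis=-1)
    w = (p * (cats - np.expand_dims(e, -1)) ** 2).sum(axis=-1)
    if np.ndim(theta) == 0:
        return float(e), float(w)
    return e, w


def reliability_from_separation(g: float) -> float:
    """Separation index G -> reliability R = G^2 / (1 + G^2)."""
    g = float(g)
    return g * g / (1.0 + g * g)


def separation_from_reliability(r: float) -> float:
    """Reliability R -> separation index G = sqrt(R / (1 - R))."""
    r = float(r)
    if not 0 <= r < 1:
        raise ValidationError(f"reliability must be in [0, 1), got {r}")
    return float(np.sqrt(r / (1.0 - r)))


@dataclass
class ItemFitStats:
    """Mean-square residual fit statistics for one item.

    Infit is information-weighted (sensitive to unexpected responses from
    persons near the item's difficulty); outfit is the unweighted mean of
    squared standardised residuals (sensitive to outlying responses from
    persons far from the item). Expectation 1 under model fit.
    """

    item_id: str
    infit_mnsq: float
    outfit_mnsq: float
    misfit: bool


@dataclass
class ScaleStats:
    """Person/item separation indices G and reliabilities R = G^2/(1+G^2)."""

    person_separation: float
    person_reliability: float
    item_separation: float
    item_reliability: float


@dataclass
class PCMResults:
    """JMLE estimates for a Partial Credit Model fit.

    ``item_steps[item_id]`` holds the estimated step difficulties (logits,
    identification: grand mean of per-item step means = 0); extreme-scoring
    persons are excluded from estimation and assigned extrapolated measures
    at pseudo-scores 0.3 / max-0.3.
    """

    item_steps: dict[str, np.ndarray]
    item_se: dict[str, np.ndarray]
    person_measures: pd.Series
    person_se: pd.Series
    converged: bool
    iterations: int
    dropped_persons: list
    rescored_items: dict[str, dict[int, int]]
    responses: ResponseMatrix = field(repr=False)
    config: RunConfig = field(repr=False)

    def fit_statistics(self) -> list[ItemFitStats]:
        return fit_statistics(self.responses, self, self.config)

    def separation_reliability(self) -> ScaleStats:
        return separation_reliability(self)

    def item_table(self) -> pd.DataFrame:
        """One row per item step: estimate, SE, plus per-item infit/outfit."""
        fits = {f.item_id: f for f in self.fit_statistics()}
        rows = []
        for item_id, steps in self.item_steps.items():
            f = fits[item_id]
            for k, (d, se) in enumerate(zip(steps, self.item_se[item_id]), 1):
                rows.append(
                    {
                        "item_id": item_id,
                        "step": k,
                        "difficulty": d,
                        "se": se,
                        "infit_mnsq": f.infit_mnsq,
                        "outfit_mnsq": f.outfit_mnsq,
                        "misfit": f.misfit,
                    }
                )
        return pd.DataFrame(rows)

    def person_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"measure": self.person_measures, "se": self.person_se}
        ).rename_axis("person")

    def summary(self) -> str:
        scale = self.separation_reliability()
        lines = [
            "Partial Credit Model (JMLE)",
            "=" * 60,
            f"persons: {len(self.person_measures)}"
            f" (extreme, extrapolated: {len(self.dropped_persons)})",
            f"items:   {len(self.item_steps)}",
            f"converged: {self.converged} after {self.iterations} iterations",
            f"person separation G={scale.person_separation:.2f}"
            f"  reliability R={scale.person_reliability:.2f}",
            f"item separation   G={scale.item_separation:.2f}"
            f"  reliability R={scale.item_reliability:.2f}",
            "-" * 60,
            f"{'item':<10}{'steps (logits)':<34}{'infit':>7}{'outfit':>8}",
        ]
        fits = {f.item_id: f for f in self.fit_statistics()}
        for item_id, steps in self.item_steps.items():
            f = fits[item_id]
            step_s = ", ".join(f"{d:+.2f}" for d in steps)
            lines.append(
                f"{item_id:<10}{step_s:<34}{f.infit_mnsq:>7.2f}{f.outfit_mnsq:>8.2f}"
            )
        return "\n".join(lines)


class PartialCreditModel:
    """Partial Credit Rasch model for a person x item ordinal response table.

    Parameters
    ----------
    responses : ResponseMatrix
        Ordinal responses; missing cells are excluded pairwise from all
        likelihood sums. Persons missing more than half their items are
        dropped with a warning.
    config : RunConfig, optional
        Convergence tolerance, iteration cap and misfit band.
    step_correction : bool
        Apply the (K-1)/K JMLE bias correction (K = number of items) to the
        final step estimates. JMLE inflates item parameters away from zero
        by roughly K/(K-1) because person parameters are estimated jointly;
        the multiplicative shrinkage removes most of it. Off by default.
    """

    def __init__(
        self,
        responses: ResponseMatrix,
        config: RunConfig | None = None,
        step_correction: bool = False,
    ):
        self.responses = responses
        self.config = config or RunConfig()
        self.step_correction = step_correction
        if len(responses.items) < 2:
            raise ValidationError("PCM needs at least 2 items")
        if len(responses.persons) < 2:
            raise ValidationError("PCM needs at least 2 persons")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        instrument: list[ItemSpec] | None = None,
        **kwargs,
    ) -> "PartialCreditModel":
        """Build from a raw person x item DataFrame; item max categories are
        taken from ``instrument`` or inferred from the observed maxima."""
        if instrument is None:
            instrument = [
                ItemSpec(str(c), max_category=max(1, int(np.nanmax(df[c]))))
                for c in df.columns
            ]
        return cls(ResponseMatrix(df, instrument), **kwargs)

    # -- estimation ---------------------------------------------------------

    def _prepare(self):
        """Drop high-missingness persons; collapse unobserved categories."""
        vals = self.responses.values.copy()
        frac_missing = vals.isna().mean(axis=1)
        drop = frac_missing > 0.5
        if drop.any():
            logger.warning(
                "dropping %d person(s) missing >50%% of items: %s",
                int(drop.sum()),
                list(vals.index[drop]),
            )
            vals = vals.loc[~drop]
        rescored: dict[str, dict[int, int]] = {}
        for it in self.responses.items:
            col = vals[it.item_id]
            observed = sorted(int(v) for v in col.dropna().unique())
            if len(observed) < 2:
                raise ValidationError(
                    f"item {it.item_id!r} has <2 observed categories; inestimable"
                )
            expected = list(range(it.max_category + 1))
            if observed != expected:
                # collapse each unobserved category into its lower neighbour
                mapping = {orig: rank for rank, orig in enumerate(observed)}
                vals[it.item_id] = col.map(lambda v: mapping[int(v)] if pd.notna(v) else np.nan)
                rescored[it.item_id] = mapping
                logger.warning(
                    "item %s re-scored (unobserved categories collapsed): %s",
                    it.item_id,
                    mapping,
                )
        return vals, rescored

    def fit(self) -> PCMResults:
        cfg = self.config
        vals, rescored = self._prepare()
        persons = vals.index
        item_ids = list(vals.columns)
        X = vals.to_numpy(dtype=float)
        n, n_items = X.shape
        obs = ~np.isnan(X)
        m = np.array([int(np.nanmax(X[:, i])) for i in range(n_items)])

        raw = np.nansum(X, axis=1)
        rmax = (obs * m[None, :]).sum(axis=1)
        extreme = (raw <= 0) | (raw >= rmax)
        if (~extreme).sum() < 2:
            raise ValidationError("fewer than 2 non-extreme persons")

        theta = np.log((raw + 0.5) / (rmax - raw + 0.5))
        steps = [np.zeros(mi) for mi in m]

        def center():
            c = float(np.mean([s.mean() for s in steps]))
            for s in steps:
                s -= c
            theta[:] = theta - c

        est = ~extreme
        it_count = 0
        converged = False
        for it_count in range(1, cfg.jmle_max_iter + 1):
            max_change = 0.0
            # item step updates: per-item multivariate Newton
            for i in range(n_items):
                use = obs[:, i] & est
                x = X[use, i]
                th = theta[use]
                p = category_probabilities(th, steps[i])  # (nu, m+1)
                # P(X >= k), k = 1..m
                pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
                sk = x[:, None] >= np.arange(1, m[i] + 1)[None, :]
                g = pge.sum(axis=0) - sk.sum(axis=0)
                # J_kl = sum_n P(X>=max(k,l)) - P(X>=k)P(X>=l)  (pos. def.)
                kk = np.maximum.outer(np.arange(m[i]), np.arange(m[i]))
                J = pge[:, kk].sum(axis=0) - pge.T @ pge
                J[np.diag_indices_from(J)] += 1e-10
                delta = np.linalg.solve(J, g)
                delta = np.clip(delta, -1.0, 1.0)
                steps[i] = steps[i] + delta
                max_change = max(max_change, float(np.abs(delta).max()))
            # person updates: scalar Newton on theta
            E = np.zeros(n)
            W = np.zeros(n)
            for i in range(n_items):
                e_i, w_i = expected_score_and_variance(theta, steps[i])
                E[obs[:, i]] += e_i[obs[:, i]]
                W[obs[:, i]] += w_i[obs[:, i]]
            upd = np.clip((raw - E) / np.maximum(W, 1e-10), -1.0, 1.0)
            theta[est] = theta[est] + upd[est]
            max_change = max(max_change, float(np.abs(upd[est]).max()))
            center()
            if max_change < cfg.jmle_tol:
                converged = True
                break
        if not converged:
            logger.warning("JMLE did not converge in %d iterations", it_count)

        if self.step_correction and n_items > 1:
            steps = [s * (n_items - 1) / n_items for s in steps]
            center()

        # standard errors
        item_se = {}
        for i, item_id in enumerate(item_ids):
            use = obs[:, i] & est
            th = theta[use]
            p = category_probabilities(th, steps[i])
            pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
            kk = np.maximum.outer(np.arange(m[i]), np.arange(m[i]))
            J = pge[:, kk].sum(axis=0) - pge.T @ pge
            J[np.diag_indices_from(J)] += 1e-10
            item_se[item_id] = np.sqrt(np.diag(np.linalg.inv(J)))

        # extreme persons: extrapolated measures at pseudo-scores 0.3 / max-0.3
        for nidx in np.where(extreme)[0]:
            target = 0.3 if raw[nidx] <= 0 else rmax[nidx] - 0.3
            theta[nidx] = self._solve_theta(target, steps, obs[nidx])

        W = np.zeros(n)
        for i in range(n_items):
            _, w_i = expected_score_and_variance(theta, steps[i])
            W[obs[:, i]] += w_i[obs[:, i]]
        person_se = 1.0 / np.sqrt(np.maximum(W, 1e-12))

        return PCMResults(
            item_steps={item_id: steps[i] for i, item_id in enumerate(item_ids)},
            item_se=item_se,
            person_measures=pd.Series(theta, index=persons, name="measure"),
            person_se=pd.Series(person_se, index=persons, name="se"),
            converged=converged,
            iterations=it_count,
            dropped_persons=list(persons[extreme]),
            rescored_items=rescored,
            responses=ResponseMatrix(vals, self.responses.items),
            config=cfg,
        )

    @staticmethod
    def _solve_theta(target: float, steps: list, observed: np.ndarray) -> float:
        """Solve sum_i E_i(theta) = target by bisection (E is monotone)."""
        idx = np.where(observed)[0]

        def total(th):
            return sum(expected_score_and_variance(th, steps[i])[0] for i in idx)

        lo, hi = -30.0, 30.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if total(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def fit_pcm(responses: ResponseMatrix, cfg: RunConfig | None = None) -> PCMResults:
    """Fit a Partial Credit Model by JMLE (convenience wrapper)."""
    return PartialCreditModel(responses, cfg).fit()


def fit_statistics(
    responses: ResponseMatrix, fit: PCMResults, cfg: RunConfig | None = None
) -> list[ItemFitStats]:
    """Mean-square infit/outfit per item from the fitted measures.

    infit_i  = sum_n (x_ni - E_ni)^2 / sum_n W_ni
    outfit_i = mean_n (x_ni - E_ni)^2 / W_ni

    Sums run over non-extreme persons with observed responses; pairs with
    W ~ 0 are excluded. Misfit is flagged when either statistic falls
    outside the configured band on either side.
    """
    cfg = cfg or fit.config
    low, high = cfg.infit_band
    vals = fit.responses.values
    theta = fit.person_measures
    estimable = ~theta.index.isin(fit.dropped_persons)
    out = []
    for item_id, steps in fit.item_steps.items():
        col = vals[item_id]
        use = col.notna().to_numpy() & estimable
        if not use.any():
            out.append(ItemFitStats(item_id, np.nan, np.nan, True))
            continue
        x = col.to_numpy(dtype=float)[use]
        th = theta.to_numpy()[use]
        e, w = expected_score_and_variance(th, steps)
        ok = w > 1e-10
        x, e, w = x[ok], e[ok], w[ok]
        if len(x) == 0:
            out.append(ItemFitStats(item_id, np.nan, np.nan, True))
            continue
        sq = (x - e) ** 2
        infit = float(sq.sum() / w.sum())
        outfit = float(np.mean(sq / w))
        misfit = not (low <= infit <= high and low <= outfit <= high)
        out.append(ItemFitStats(item_id, infit, outfit, misfit))
    return out


def separation_reliability(fit: PCMResults) -> ScaleStats:
    """Person and item separation/reliability from estimates and their SEs.

    R = (observed variance - mean error variance) / observed variance,
    G = sqrt(R / (1 - R)); item statistics pool all step estimates.
    """

    def _sep(values: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
        if len(values) < 2:
            return 0.0, 0.0
        var = float(np.var(values, ddof=1))
        if var <= 0:
            return 0.0, 0.0
        mse = float(np.mean(ses**2))
        adj = max(0.0, var - mse)
        r = adj / var
        g = separation_from_reliability(min(r, 1 - 1e-12))
        return g, r

    est_mask = ~fit.person_measures.index.isin(fit.dropped_persons)
    gp, rp = _sep(
        fit.person_measures.to_numpy()[est_mask], fit.person_se.to_numpy()[est_mask]
    )
    all_steps = np.concatenate([fit.item_steps[i] for i in fit.item_steps])
    all_ses = np.concatenate([fit.item_se[i] for i in fit.item_steps])
    gi, ri = _sep(all_steps, all_ses)
    return ScaleStats(gp, rp, gi, ri)


def fit_by_subscale(
    responses: ResponseMatrix, cfg: RunConfig | None = None
) -> dict[str, PCMResults]:
    """Separate unidimensional PCM fits per subscale (ordinal items only,
    subscales with >= 2 items)."""
    out = {}
    for sub in dict.fromkeys(it.subscale for it in responses.items):
        ids = [
            it.item_id
            for it in responses.items
            if it.subscale == sub and not it.is_binary
        ]
        if len(ids) < 2:
            continue
        out[sub] = fit_pcm(responses.subset(ids), cfg)
    return out
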