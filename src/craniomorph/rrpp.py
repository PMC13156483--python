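"""Permutation MANCOVA for shape scores by residual randomization (RRPP).

A linear model of multivariate shape scores on categorical factors and a
log-centroid-size covariate, with per-term type III sums of squares assessed
against a null distribution built by randomizing the residuals of the
term-reduced model. Includes backward model reduction, pairwise group-mean
distances, and pairwise allometric-slope comparison.

The entry point follows the fitted-model idiom:
``ShapeMANCOVA(scores, design, terms).fit(iterations=..., seed=...)`` returns
a :class:`MANCOVAResults` with a per-term ANOVA-style table, ``summary()``,
and the pairwise tests hanging off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _count_ge(value: float, observed: float) -> bool:
    """Permutation tail comparison with a tie tolerance (floating-point safe)."""
    return value >= observed - 1e-12 * (1.0 + abs(observed))


class CollinearDesignError(ValueError):
    """The design matrix has aliased terms; ``aliased`` names them."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


# ---------------------------------------------------------------------------
# Design matrices: sum-to-zero contrasts, interactions as column products
# ---------------------------------------------------------------------------

def _contrast_columns(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} has a single level")
    cols = np.zeros((len(values), len(levels) - 1))
    vals = values.astype(str).to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(vals == lev, 1.0, np.where(vals == levels[-1], -1.0, 0.0))
    names = [f"{values.name}[{lev}]" for lev in levels[:-1]]
    return cols, names


def build_design(data: pd.DataFrame, terms: Sequence[str],
                 covariates: Sequence[str] = ()) -> tuple[np.ndarray, dict[str, slice]]:
    """Design matrix with intercept, sum-contrast factors, centered covariates,
    and interaction terms written ``a:b``. Returns (X, {term: column slice})."""
    n = len(data)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    spans: dict[str, slice] = {}
    start = 1
    main_cols: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            missing = [p for p in parts if p not in main_cols]
            if missing:
                raise ValueError(f"interaction {term!r} requires main-effect terms "
                                 f"{missing} to appear first")
            cols = main_cols[parts[0]]
            for p in parts[1:]:
                other = main_cols[p]
                cols = np.concatenate(
                    [cols[:, [i]] * other for i in range(cols.shape[1])], axis=1)
        elif term in covariates:
            vals = data[term].to_numpy(float)
            cols = (vals - vals.mean())[:, None]
        else:
            cols, _ = _contrast_columns(data[term])
            main_cols[term] = cols
        if term in covariates:
            main_cols[term] = cols
        blocks.append(cols)
        spans[term] = slice(start, start + cols.shape[1])
        start += cols.shape[1]
    x = np.concatenate(blocks, axis=1)
    return x, spans


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-10)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError("rank deficient")
    return q @ q.T


def _check_collinear(x: np.ndarray, spans: Mapping[str, slice]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        aliased = []
        current = x[:, :1]
        for term, span in spans.items():
            candidate = np.concatenate([current, x[:, span]], axis=1)
            if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
                aliased.append(term)
            else:
                current = candidate
        raise CollinearDesignError(f"design is collinear; aliased terms: {aliased}",
                                   aliased)


# ---------------------------------------------------------------------------
# The RRPP model
# ---------------------------------------------------------------------------

@dataclass
class MANCOVAResults:
    """Per-term type III permutation ANOVA table plus fit internals."""

    table: pd.DataFrame           # index: term; columns: df, SS, MS, F, Z, p
    terms: list[str]
    covariates: list[str]
    iterations: int
    seed: int
    n_obs: int
    residual_df: int
    residual_ss: float
    model: "ShapeMANCOVA" = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Permutation MANCOVA (residual randomization, type III SS)",
            f"  observations: {self.n_obs}   iterations: {self.iterations} "
            f"(+ observed)   seed: {self.seed}",
            "",
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            f"  residual df: {self.residual_df}   residual SS: {self.residual_ss:.4f}",
        ]
        return "\n".join(lines)

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        return [t for t in self.table.index if self.table.loc[t, "p"] <= alpha]

    def pairwise_means(self, group: str, *, iterations: int | None = None,
                       seed: int | None = None, confidence: float = 0.95
                       ) -> pd.DataFrame:
        return self.model.pairwise_means(group, iterations=iterations or self.iterations,
                                         seed=self.seed if seed is None else seed,
                                         confidence=confidence)

    def pairwise_slopes(self, group: str, covariate: str, *,
                        iterations: int | None = None, seed: int | None = None,
                        confidence: float = 0.95) -> pd.DataFrame:
        return self.model.pairwise_slopes(group, covariate,
                                          iterations=iterations or self.iterations,
                                          seed=self.seed if seed is None else seed,
                                          confidence=confidence)


class ShapeMANCOVA:
    """Multivariate linear model of shape scores with RRPP inference.

    Parameters
    ----------
    responses : (n, p) array
        Shape scores (typically the retained principal components).
    design : DataFrame
        One row per observation: factor columns and covariate columns.
    terms : sequence of str
        Model terms in fitting order; interactions as ``"a:b"`` after their
        main effects.
    covariates : sequence of str
        Names among ``terms`` treated as numeric covariates (centered).
    """

    def __init__(self, responses: np.ndarray, design: pd.DataFrame,
                 terms: Sequence[str], covariates: Sequence[str] = ()):
        y = np.asarray(responses, float)
        if y.ndim == 1:
            y = y[:, None]
        if len(design) != y.shape[0]:
            raise ValueError("responses and design have different lengths")
        self.y = y
        self.design = design.reset_index(drop=True)
        self.terms = list(terms)
        self.covariates = [c for c in covariates if c in self.terms]
        self._x, self._spans = build_design(self.design, self.terms, self.covariates)
        _check_collinear(self._x, self._spans)

    # -- helpers -----------------------------------------------------------
    def _reduced_x(self, drop_term: str) -> np.ndarray:
        keep = [i for i in range(self._x.shape[1])]
        span = self._spans[drop_term]
        keep = [i for i in keep if not (span.start <= i < span.stop)]
        return self._x[:, keep]

    def fit(self, *, iterations: int = 10_000, seed: int = 0,
            permutations: Sequence[np.ndarray] | None = None) -> MANCOVAResults:
        y = self.y
        n = y.shape[0]
        h_full = _hat(self._x)
        rss_full = float(np.sum((y - h_full @ y) ** 2))
        df_res = n - np.linalg.matrix_rank(self._x)
        if permutations is not None:
            perms = [np.asarray(p) for p in permutations]
            iterations = len(perms)
        else:
            rng = np.random.default_rng(seed)
            perms = [rng.permutation(n) for _ in range(iterations)]

        rows = []
        for term in self.terms:
            x_red = self._reduced_x(term)
            h_red = _hat(x_red)
            df_term = self._spans[term].stop - self._spans[term].start
            fitted_red = h_red @ y
            resid_red = y - fitted_red
            ss_obs = float(np.sum(resid_red**2)) - rss_full
            ms_res = rss_full / df_res if df_res > 0 else np.nan
            f_obs = (ss_obs / df_term) / ms_res if ms_res else np.nan
            f_perm = np.empty(iterations)
            with np.errstate(invalid="ignore", divide="ignore"):
                for b, perm in enumerate(perms):
                    y_star = fitted_red + resid_red[perm]
                    rss_red_star = float(np.sum((y_star - h_red @ y_star) ** 2))
                    rss_full_star = float(np.sum((y_star - h_full @ y_star) ** 2))
                    ss_star = rss_red_star - rss_full_star
                    f_perm[b] = (ss_star / df_term) / (rss_full_star / df_res)
            count = 1 + int(np.sum(f_perm >= f_obs - 1e-12 * (1.0 + abs(f_obs))))
            p = count / (iterations + 1)
            spread = f_perm.std(ddof=1)
            z = (f_obs - f_perm.mean()) / spread if spread > 0 else np.nan
            rows.append({"term": term, "df": df_term, "SS": ss_obs,
                         "MS": ss_obs / df_term, "F": f_obs, "Z": z, "p": p})
        table = pd.DataFrame(rows).set_index("term")
        return MANCOVAResults(table=table, terms=list(self.terms),
                              covariates=list(self.covariates),
                              iterations=iterations, seed=seed, n_obs=n,
                              residual_df=df_res, residual_ss=rss_full, model=self)

    # -- pairwise tests ----------------------------------------------------
    def _group_labels(self, group: str) -> np.ndarray:
        return self.design[group].astype(str).to_numpy()

    def pairwise_means(self, group: str, *, iterations: int = 10_000, seed: int = 0,
                       confidence: float = 0.95) -> pd.DataFrame:
        """Euclidean distances between least-squares group means with RRPP p-values.

        The null model drops ``group`` (keeping all other terms); distances on
        residual-randomized datasets form the reference distribution.
        """
        labels = self._group_labels(group)
        levels, counts = np.unique(labels, return_counts=True)
        if len(levels) < 2:
            raise ValueError(f"pairwise means needs >= 2 levels of {group!r}")
        singletons = levels[counts < 2]
        if singletons.size:
            warnings.warn(f"groups with n = 1 excluded from pairwise means: "
                          f"{list(singletons)}")
            levels = levels[counts >= 2]

        def distances(y: np.ndarray) -> dict[tuple[str, str], float]:
            means = {lev: y[labels == lev].mean(axis=0) for lev in levels}
            return {(a, b): float(np.linalg.norm(means[a] - means[b]))
                    for a, b in combinations(levels, 2)}

        d_obs = distances(self.y)
        x_red = self._reduced_x(group)
        h_red = _hat(x_red)
        fitted = h_red @ self.y
        resid = self.y - fitted
        rng = np.random.default_rng(seed)
        counts_ge = {pair: 1 for pair in d_obs}
        for _ in range(iterations):
            y_star = fitted + resid[rng.permutation(len(resid))]
            d_star = distances(y_star)
            for pair in d_obs:
                if _count_ge(d_star[pair], d_obs[pair]):
                    counts_ge[pair] += 1
        rows = [{"group_a": a, "group_b": b, "distance": d_obs[(a, b)],
                 "p": counts_ge[(a, b)] / (iterations + 1),
                 "significant": counts_ge[(a, b)] / (iterations + 1) <= 1 - confidence,
                 "confidence": confidence}
                for a, b in d_obs]
        return pd.DataFrame(rows)

    def pairwise_slopes(self, group: str, covariate: str, *, iterations: int = 10_000,
                        seed: int = 0, confidence: float = 0.95) -> pd.DataFrame:
        """Pairwise comparison of per-group shape-vs-size slope vectors.

        Per group, the slope vector is the multivariate regression coefficient
        of the responses on the centered covariate within that group. Pairs
        are compared by the angle between slope vectors (degrees) and the
        difference of their lengths; the null randomizes residuals of the
        common-slope model (``group`` + ``covariate``, no interaction).
        """
        labels = self._group_labels(group)
        levels = np.unique(labels)
        cov = self.design[covariate].to_numpy(float)

        def slopes(y: np.ndarray) -> dict[str, np.ndarray]:
            out = {}
            for lev in levels:
                mask = labels == lev
                c = cov[mask] - cov[mask].mean()
                denom = np.sum(c * c)
                if denom == 0:
                    raise ValueError(f"group {lev!r} has no size variation")
                out[lev] = (c @ y[mask]) / denom
            return out

        def stats(sl: dict[str, np.ndarray]) -> dict[tuple[str, str], tuple[float, float]]:
            res = {}
            for a, b in combinations(levels, 2):
                va, vb = sl[a], sl[b]
                na, nb = np.linalg.norm(va), np.linalg.norm(vb)
                if na == 0 or nb == 0:
                    angle = 0.0
                else:
                    angle = float(np.degrees(np.arccos(
                        np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))))
                res[(a, b)] = (angle, float(abs(na - nb)))
            return res

        obs = stats(slopes(self.y))
        # Null model: common slope (all terms except the group x size interaction).
        inter = f"{group}:{covariate}"
        null_terms = [t for t in self.terms if t != inter]
        if inter not in self.terms:
            null_terms = self.terms
        x_red, _ = build_design(self.design, null_terms, self.covariates)
        h_red = _hat(x_red)
        fitted = h_red @ self.y
        resid = self.y - fitted
        rng = np.random.default_rng(seed)
        counts_angle = {pair: 1 for pair in obs}
        counts_len = {pair: 1 for pair in obs}
        for _ in range(iterations):
            y_star = fitted + resid[rng.permutation(len(resid))]
            star = stats(slopes(y_star))
            for pair in obs:
                if _count_ge(star[pair][0], obs[pair][0]):
                    counts_angle[pair] += 1
                if _count_ge(star[pair][1], obs[pair][1]):
                    counts_len[pair] += 1
        rows = [{"group_a": a, "group_b": b,
                 "angle_deg": obs[(a, b)][0], "length_diff": obs[(a, b)][1],
                 "p_angle": counts_angle[(a, b)] / (iterations + 1),
                 "p_length": counts_len[(a, b)] / (iterations + 1),
                 "significant": min(counts_angle[(a, b)], counts_len[(a, b)])
                 / (iterations + 1) <= 1 - confidence,
                 "confidence": confidence}
                for a, b in obs]
        return pd.DataFrame(rows)


def reduce_model(responses: np.ndarray, design: pd.DataFrame, terms: Sequence[str],
                 *, covariates: Sequence[str] = (), protected: Sequence[str] = (),
                 alpha: float = 0.05, iterations: int = 999, seed: int = 0
                 ) -> tuple[list[str], MANCOVAResults]:
    """Backward elimination of non-significant terms by RRPP p-value.

    Repeatedly drops the highest-p non-significant term, removing interactions
    before the main effects they contain (a main effect becomes droppable only
    when none of its interactions remain). Covariates listed in ``protected``
    are never dropped. Returns the final term list and its fitted results.
    """
    protected = set(protected) | set()
    current = list(terms)
    rng = np.random.default_rng(seed)
    while True:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        result = ShapeMANCOVA(responses, design, current, covariates).fit(
            iterations=iterations, seed=sub_seed)
        pvals = result.table["p"]
        droppable = []
        for term in current:
            if term in protected:
                continue
            if pvals[term] <= alpha:
                continue
            has_interaction = any(
                ":" in other and term in other.split(":") for other in current
                if other != term)
            if ":" not in term and has_interaction:
                continue
            droppable.append(term)
        if not droppable:
            return current, result
        # interactions drop before main effects even at a smaller p; a main
        # effect is only in `droppable` once none of its interactions remain
        interactions = [t for t in droppable if ":" in t]
        pool = interactions if interactions else droppable
        worst = max(pool, key=lambda t: pvals[t])
        current = [t for t in current if t != worst]
        if not current:
            return current, result
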