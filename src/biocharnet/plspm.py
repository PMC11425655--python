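"""Partial least squares path modelling (Lohmöller algorithm).

Latent blocks are measured reflectively (mode A) by named manifest
indicators; the inner model is a recursive (acyclic) path structure.  Outer
weights start at one and iterate: latent scores are standardised weighted
indicator sums; inner estimates follow the centroid scheme (each latent's
inner proxy is the sign-weighted sum of its neighbours' scores); mode-A
weights are refreshed as indicator-proxy correlations, until the largest
weight change falls below tolerance.  Path coefficients are then OLS
regressions of each endogenous latent on its predecessors; the goodness of
fit is

    GoF = sqrt(mean communality x mean R^2)

with communality the mean squared loading of a block.  Bootstrap resampling
(with per-replicate sign alignment against the base fit) yields standard
errors and percentile intervals for the paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PathModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, last_delta: float):
        super().__init__(message)
        self.last_delta = last_delta


@dataclass
class PathModel:
    """Latent blocks (name -> indicator columns) and directed paths.

    Block order must be causal: every path must point from an earlier block
    to a later one (lower-triangular inner matrix), which guarantees
    acyclicity.
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]

    def __post_init__(self) -> None:
        order = {b: i for i, b in enumerate(self.blocks)}
        seen: set[str] = set()
        for block, inds in self.blocks.items():
            if not inds:
                raise PathModelError(f"block {block!r} has no indicators")
            dup = seen.intersection(inds)
            if dup:
                raise PathModelError(f"indicator(s) in several blocks: {sorted(dup)}")
            seen.update(inds)
        for src, dst in self.paths:
            if src not in order or dst not in order:
                raise PathModelError(f"path {src}->{dst} references unknown block")
            if order[src] >= order[dst]:
                raise PathModelError(
                    f"path {src}->{dst} violates the causal block order"
                )

    def predecessors(self, block: str) -> list[str]:
        return [s for s, d in self.paths if d == block]

    def neighbours(self, block: str) -> list[str]:
        out = [d for s, d in self.paths if s == block]
        return self.predecessors(block) + out

    @property
    def endogenous(self) -> list[str]:
        return [b for b in self.blocks if self.predecessors(b)]


def biochar_path_model(
    soil_indicators: list[str] | None = None,
    diversity_indicators: list[str] | None = None,
) -> PathModel:
    """Default causal structure of the biochar - soil - microbiome system.

    Biochar (binary treatment) acts on soil properties and directly on
    p-coumaric acid; soil properties drive microbial diversity and hub-genus
    abundance; both feed the aromatic-compound-degradation (ACD) function,
    which in turn affects p-coumaric acid.
    """
    return PathModel(
        blocks={
            "Biochar": ["biochar"],
            "Soil": soil_indicators or ["pH", "SOM"],
            "Diversity": diversity_indicators or ["Shannon"],
            "HubGenera": ["hub_abundance"],
            "ACD": ["acd_abundance"],
            "pCA": ["p_CA"],
        },
        paths=[
            ("Biochar", "Soil"),
            ("Biochar", "pCA"),
            ("Soil", "Diversity"),
            ("Soil", "HubGenera"),
            ("Diversity", "ACD"),
            ("HubGenera", "ACD"),
            ("ACD", "pCA"),
        ],
    )


@dataclass
class PathFit:
    model: PathModel
    loadings: pd.Series                 # per indicator
    weights: pd.Series                  # outer weights, per indicator
    scores: pd.DataFrame                # latent scores, unit variance
    paths: pd.DataFrame                 # rows: "src->dst" with coefficient
    r_squared: dict[str, float]
    communality: dict[str, float]
    gof: float
    n_iter: int
    bootstrap: pd.DataFrame | None = None


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise PathModelError("constant indicator column")
    return (x - x.mean(axis=0)) / sd


def fit_plspm(
    data: pd.DataFrame,
    model: PathModel,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PathFit:
    """Estimate a PLS path model by the Lohmöller algorithm.

    Indicators are standardised internally; centroid inner scheme, mode-A
    outer estimation.  When every block has a single indicator the outer
    iteration is bypassed (weights fixed at one).  Raises
    :class:`ConvergenceError` carrying the last weight change when the
    iteration does not settle within ``max_iter``.
    """
    missing = [c for inds in model.blocks.values() for c in inds if c not in data]
    if missing:
        raise PathModelError(f"data lacks indicator column(s): {missing[:5]}")
    widest = max((len(model.predecessors(b)) for b in model.blocks), default=0)
    if len(data) < widest + 2:
        raise PathModelError("too few samples for the widest inner regression")

    names = list(model.blocks)
    x = {b: _standardize(data[model.blocks[b]].to_numpy(dtype=float)) for b in names}
    w = {b: np.ones(len(model.blocks[b])) for b in names}

    def scores_from(wts):
        sc = {}
        for b in names:
            y = x[b] @ wts[b]
            sd = y.std(ddof=1)
            if sd == 0:
                raise PathModelError(f"degenerate latent score for block {b!r}")
            sc[b] = (y - y.mean()) / sd
        return sc

    y = scores_from(w)
    n_iter = 0
    multi = any(len(inds) > 1 for inds in model.blocks.values())
    delta = 0.0
    if multi:
        for n_iter in range(1, max_iter + 1):
            # centroid scheme inner proxies
            z = {}
            for b in names:
                nb = model.neighbours(b)
                if not nb:
                    z[b] = y[b]
                    continue
                acc = np.zeros(len(data))
                for o in nb:
                    sgn = np.sign(np.corrcoef(y[b], y[o])[0, 1]) or 1.0
                    acc += sgn * y[o]
                z[b] = acc
            w_new = {}
            for b in names:
                if len(model.blocks[b]) == 1:
                    w_new[b] = np.ones(1)
                    continue
                zb = z[b]
                zsd = zb.std(ddof=1)
                zb = (zb - zb.mean()) / zsd if zsd > 0 else zb
                w_new[b] = np.array(
                    [np.corrcoef(x[b][:, i], zb)[0, 1] for i in range(x[b].shape[1])]
                )
            delta = max(
                float(np.max(np.abs(np.abs(w_new[b]) - np.abs(w[b]))))
                for b in names
            )
            w = w_new
            y = scores_from(w)
            if delta < tol:
                break
        else:
            raise ConvergenceError(
                f"outer weights did not converge in {max_iter} iterations "
                f"(last delta {delta:.3e})", delta,
            )

    loadings = {}
    communality = {}
    for b in names:
        ls = [float(np.corrcoef(x[b][:, i], y[b])[0, 1]) for i in range(x[b].shape[1])]
        for ind, l in zip(model.blocks[b], ls):
            loadings[ind] = l
        communality[b] = float(np.mean(np.square(ls)))

    paths = {}
    r2 = {}
    for b in model.endogenous:
        preds = model.predecessors(b)
        xm = np.column_stack([y[p] for p in preds])
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(data)), xm]), y[b], rcond=None
        )
        fitted = np.column_stack([np.ones(len(data)), xm]) @ coef
        r2[b] = float(1.0 - np.sum((y[b] - fitted) ** 2) / np.sum((y[b] - y[b].mean()) ** 2))
        for p, c in zip(preds, coef[1:]):
            paths[f"{p}->{b}"] = float(c)

    mean_comm = float(np.mean(list(communality.values())))
    mean_r2 = float(np.mean(list(r2.values()))) if r2 else 0.0
    gof = float(np.sqrt(max(mean_comm, 0.0) * max(mean_r2, 0.0)))
    return PathFit(
        model=model,
        loadings=pd.Series(loadings, name="loading"),
        weights=pd.Series(
            {ind: w[b][i] for b in names for i, ind in enumerate(model.blocks[b])},
            name="weight",
        ),
        scores=pd.DataFrame({b: y[b] for b in names}, index=data.index),
        paths=pd.DataFrame.from_dict(paths, orient="index", columns=["coefficient"]),
        r_squared=r2,
        communality=communality,
        gof=gof,
        n_iter=n_iter,
    )


def prune_by_loading(
    data: pd.DataFrame,
    model: PathModel,
    threshold: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[PathModel, PathFit]:
    """Drop indicators with |loading| <= threshold and refit until stable.

    A block emptied of indicators is removed with its paths when nothing
    downstream depends on it; emptying a block that other paths require is
    an error naming the block.
    """
    current = model
    while True:
        fit = fit_plspm(data, current, tol=tol, max_iter=max_iter)
        weak = [
            ind for ind, l in fit.loadings.items() if abs(l) <= threshold
        ]
        if not weak:
            return current, fit
        blocks = {
            b: [i for i in inds if i not in weak]
            for b, inds in current.blocks.items()
        }
        emptied = [b for b, inds in blocks.items() if not inds]
        for b in emptied:
            if any(s == b for s, _ in current.paths) and any(
                d == b for _, d in current.paths
            ):
                raise PathModelError(
                    f"pruning emptied block {b!r}, which other paths require"
                )
            if any(s == b for s, _ in current.paths):
                # source-only block: removing it removes explanatory paths
                raise PathModelError(
                    f"pruning emptied block {b!r}, which other paths require"
                )
        blocks = {b: inds for b, inds in blocks.items() if inds}
        paths = [
            (s, d) for s, d in current.paths if s in blocks and d in blocks
        ]
        current = PathModel(blocks=blocks, paths=paths)


def bootstrap_paths(
    data: pd.DataFrame,
    model: PathModel,
    n_boot: int = 1000,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Bootstrap path coefficients: SE, percentile CI and empirical p.

    Samples are resampled with replacement; each replicate's latent signs
    are aligned to the base fit through the loading pattern before its paths
    are collected.  A warning reports replicate non-convergence above 10%.
    """
    base = fit_plspm(data, model, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    names = list(model.blocks)
    collected: dict[str, list[float]] = {p: [] for p in base.paths.index}
    failures = 0
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            fit = fit_plspm(sample, model, tol=tol, max_iter=max_iter)
        except (ConvergenceError, PathModelError):
            failures += 1
            continue
        sign = {}
        for b in names:
            inds = model.blocks[b]
            dot = float(
                np.dot(fit.loadings[inds].to_numpy(), base.loadings[inds].to_numpy())
            )
            sign[b] = -1.0 if dot < 0 else 1.0
        for key in collected:
            src, dst = key.split("->")
            if key in fit.paths.index:
                collected[key].append(
                    float(fit.paths.loc[key, "coefficient"]) * sign[src] * sign[dst]
                )
    if failures > 0.1 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap replicates failed to converge",
            stacklevel=2,
        )
    rows = {}
    for key, vals in collected.items():
        arr = np.asarray(vals, dtype=float)
        est = float(base.paths.loc[key, "coefficient"])
        if arr.size == 0:
            rows[key] = {"estimate": est, "boot_mean": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n_boot": 0}
            continue
        frac_pos = float(np.mean(arr > 0))
        p_emp = 2.0 * min(frac_pos, 1.0 - frac_pos)
        rows[key] = {
            "estimate": est,
            "boot_mean": float(arr.mean()),
            "se": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "ci_low": float(np.percentile(arr, 2.5)),
            "ci_high": float(np.percentile(arr, 97.5)),
            "p": p_emp,
            "n_boot": int(arr.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
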