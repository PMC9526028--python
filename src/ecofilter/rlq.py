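"""Criterion III: RLQ coupled ordination and the sequential permutation test.

Three separate analyses feed the coupled one:

* correspondence analysis of the site-by-species abundance table L, whose
  site and species masses become the row weights of the other two tables;
* a weighted PCA of the quantitative environment table R (columns
  standardized under the site masses);
* a Hill-Smith ordination of the mixed trait table Q (quantitative columns
  as weighted z-scores with unit column metric; each nominal level as the
  transformed indicator 1[x=m]/p_m - 1 with column metric p_m, the
  weighted level frequency). Hill-Smith reduces to weighted PCA when all
  columns are quantitative and to multiple correspondence analysis when
  all are nominal.

RLQ decomposes the cross matrix M = Z_R' D_r L0 D_c Z_Q in the two column
metrics; its eigenvalues are squared singular values and their sum (the
total co-inertia) is the test statistic of the sequential permutation
test: model 2 permutes species against traits, model 4 permutes sites
against environment, and association is claimed only when both reject
(combined p = max of the two).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecofilter.data_model import CommunityMatrix, SiteTable, TraitTable


@dataclass
class CAResult:
    row_weights: np.ndarray       # site masses r, sum 1
    col_weights: np.ndarray       # species masses c, sum 1
    standardized: np.ndarray      # L0 with entries p_ij/(r_i c_j) - 1
    eigenvalues: np.ndarray
    row_scores: np.ndarray        # principal coordinates (sites x axes)
    col_scores: np.ndarray        # principal coordinates (species x axes)
    site_ids: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)


@dataclass
class OrdinationTriplet:
    table: np.ndarray             # transformed table Z
    row_weights: np.ndarray
    col_metric: np.ndarray        # one weight per column of Z
    columns: list[str] = field(default_factory=list)


@dataclass
class RLQResult:
    eigenvalues: np.ndarray
    total_coinertia: float
    cross_matrix: np.ndarray           # env columns x trait columns
    env_scores: pd.DataFrame           # environment variable loadings
    trait_scores: pd.DataFrame         # trait column loadings
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    species_scores_normed: pd.DataFrame


@dataclass
class PermTestResult:
    model: str
    observed: float
    n_perm: int
    permuted: np.ndarray
    p_value: float


def correspondence_analysis(cm: CommunityMatrix) -> CAResult:
    """CA of the abundance table via SVD of D_r^1/2 L0 D_c^1/2."""
    L = np.asarray(cm.abundance, dtype=float)
    total = L.sum()
    if total <= 0:
        raise ValueError("total abundance is zero")
    if np.any(L.sum(axis=1) == 0):
        bad = [cm.site_ids[i] for i in np.flatnonzero(L.sum(axis=1) == 0)]
        raise ValueError(f"all-zero rows (filter these sites first): {bad}")
    if np.any(L.sum(axis=0) == 0):
        bad = [cm.species_ids[j] for j in np.flatnonzero(L.sum(axis=0) == 0)]
        raise ValueError(f"all-zero columns (filter these species first): {bad}")
    P = L / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    L0 = P / np.outer(r, c) - 1.0
    S = np.sqrt(r)[:, None] * L0 * np.sqrt(c)[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    eig = sv**2
    row_scores = (U / np.sqrt(r)[:, None]) * sv
    col_scores = (Vt.T / np.sqrt(c)[:, None]) * sv
    return CAResult(r, c, L0, eig, row_scores, col_scores,
                    list(cm.site_ids), list(cm.species_ids))


def _weighted_standardize(x: np.ndarray, w: np.ndarray,
                          name: str = "column") -> np.ndarray:
    mean = float(w @ x)
    centered = x - mean
    var = float(w @ centered**2)
    if var <= 0:
        raise ValueError(f"zero weighted variance in {name}")
    return centered / np.sqrt(var)


def weighted_pca_env(env: pd.DataFrame,
                     row_weights: np.ndarray) -> OrdinationTriplet:
    """Environment table as weighted z-scores with identity column metric."""
    w = np.asarray(row_weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        w = w / w.sum()
    cols = list(env.columns)
    Z = np.column_stack([
        _weighted_standardize(env[c].to_numpy(dtype=float), w, repr(c))
        for c in cols
    ])
    return OrdinationTriplet(Z, w, np.ones(len(cols)), cols)


def hill_smith(traits: TraitTable, row_weights: np.ndarray) -> OrdinationTriplet:
    """Mixed-variable ordination table for the traits."""
    w = np.asarray(row_weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        w = w / w.sum()
    if len(w) != len(traits.species_ids):
        raise ValueError("row weights must match the number of species")
    blocks: list[np.ndarray] = []
    metrics: list[float] = []
    names: list[str] = []
    for name in traits.trait_names:
        col = traits.traits[name]
        if traits.variable_spec[name]["kind"] == "continuous":
            z = _weighted_standardize(
                pd.to_numeric(col).to_numpy(dtype=float), w, repr(name))
            blocks.append(z[:, None])
            metrics.append(1.0)
            names.append(name)
        else:
            x = col.astype(str).to_numpy()
            for level in pd.unique(x):
                ind = (x == level).astype(float)
                p_m = float(w @ ind)
                if p_m <= 0:
                    warnings.warn(
                        f"level {level!r} of {name!r} has zero weighted "
                        "frequency; dropped", stacklevel=2)
                    continue
                blocks.append((ind / p_m - 1.0)[:, None])
                metrics.append(p_m)
                names.append(f"{name}[{level}]")
    Z = np.hstack(blocks)
    return OrdinationTriplet(Z, w, np.asarray(metrics), names)


def _cross_matrix(env_t: OrdinationTriplet, ca: CAResult,
                  trait_t: OrdinationTriplet) -> np.ndarray:
    # W = D_r L0 D_c = P - r c'
    W = (ca.row_weights[:, None] * ca.standardized * ca.col_weights[None, :])
    return env_t.table.T @ W @ trait_t.table


def rlq(env_t: OrdinationTriplet, ca: CAResult,
        trait_t: OrdinationTriplet) -> RLQResult:
    """Generalized SVD of the cross matrix in the two column metrics."""
    if env_t.table.shape[0] != len(ca.row_weights):
        raise ValueError("environment rows do not match abundance sites")
    if trait_t.table.shape[0] != len(ca.col_weights):
        raise ValueError("trait rows do not match abundance species")
    M = _cross_matrix(env_t, ca, trait_t)
    dR = np.sqrt(env_t.col_metric)
    dQ = np.sqrt(trait_t.col_metric)
    A = dR[:, None] * M * dQ[None, :]
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    eig = sv**2
    # loadings with unit norm under each column metric
    env_axes = U / dR[:, None]
    trait_axes = Vt.T / dQ[:, None]
    site_scores = env_t.table @ (env_t.col_metric[:, None] * env_axes)
    species_scores = trait_t.table @ (trait_t.col_metric[:, None] * trait_axes)
    c = ca.col_weights
    norms = np.sqrt(c @ species_scores**2)
    normed = np.divide(species_scores, norms,
                       out=np.zeros_like(species_scores), where=norms > 0)
    axes = [f"axis{k + 1}" for k in range(len(sv))]
    return RLQResult(
        eigenvalues=eig,
        total_coinertia=float((A**2).sum()),
        cross_matrix=M,
        env_scores=pd.DataFrame(env_axes, index=env_t.columns, columns=axes),
        trait_scores=pd.DataFrame(trait_axes, index=trait_t.columns,
                                  columns=axes),
        site_scores=pd.DataFrame(site_scores, index=ca.site_ids, columns=axes),
        species_scores=pd.DataFrame(species_scores, index=ca.species_ids,
                                    columns=axes),
        species_scores_normed=pd.DataFrame(normed, index=ca.species_ids,
                                           columns=axes),
    )


def total_coinertia(env_t: OrdinationTriplet, ca: CAResult,
                    trait_t: OrdinationTriplet) -> float:
    """Metric-weighted squared norm of the cross matrix (no SVD needed)."""
    M = _cross_matrix(env_t, ca, trait_t)
    return float(np.einsum("i,ij,j->", env_t.col_metric, M**2,
                           trait_t.col_metric))


def run_rlq(cm: CommunityMatrix, sites: SiteTable, traits: TraitTable,
            scale: int = 250) -> RLQResult:
    """Convenience wrapper: CA on L, weighted PCA on R, Hill-Smith on Q."""
    ca = correspondence_analysis(cm)
    env = sites.subset(cm.site_ids).covariates(scale)
    env_t = weighted_pca_env(env, ca.row_weights)
    trait_t = hill_smith(traits.subset(cm.species_ids), ca.col_weights)
    return rlq(env_t, ca, trait_t)


def permutation_test(
    cm: CommunityMatrix,
    sites: SiteTable,
    traits: TraitTable,
    model: str,
    n_perm: int = 49999,
    scale: int = 250,
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Sequential-test component for one permutation model.

    model2 permutes species identities against the trait table (the
    trait-link test); model4 permutes site identities against the
    environment table (the environment-link test). The abundance table
    and its CA masses stay fixed, so each permutation re-pairs the masses
    with permuted covariate/trait rows and re-standardizes. One-tailed
    upper p with add-one correction.
    """
    if model not in ("model2", "model4"):
        raise ValueError(f"model must be 'model2' or 'model4', got {model!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gen = np.random.default_rng(rng)
    ca = correspondence_analysis(cm)
    env = sites.subset(cm.site_ids).covariates(scale)
    traits = traits.subset(cm.species_ids)
    env_t = weighted_pca_env(env, ca.row_weights)
    trait_t = hill_smith(traits, ca.col_weights)
    obs = total_coinertia(env_t, ca, trait_t)
    W = (ca.row_weights[:, None] * ca.standardized
         * ca.col_weights[None, :])
    permuted = np.empty(n_perm)
    if model == "model2":
        raw = _raw_trait_columns(traits)
        w = ca.col_weights
        WH = W.T @ env_t.table  # (species x env cols), reused every draw
        for k in range(n_perm):
            perm = gen.permutation(len(w))
            Z, metric = _standardize_raw(raw, w, perm)
            M = WH.T @ Z
            permuted[k] = float(np.einsum(
                "i,ij,j->", env_t.col_metric, M**2, metric))
    else:
        raw_env = env.to_numpy(dtype=float)
        w = ca.row_weights
        # carry sqrt of the trait metric so Frobenius norm gives co-inertia
        WZ = W @ (trait_t.table * np.sqrt(trait_t.col_metric)[None, :])
        for k in range(n_perm):
            perm = gen.permutation(len(w))
            x = raw_env[perm]
            xc = x - w @ x
            sd = np.sqrt(w @ xc**2)
            if np.any(sd <= 0):
                raise ValueError("zero weighted variance under permutation")
            M = (xc / sd).T @ WZ
            permuted[k] = float((M**2).sum())
    p = (1 + int((permuted >= obs - 1e-15).sum())) / (n_perm + 1)
    return PermTestResult(model, obs, n_perm, permuted, float(p))


def _raw_trait_columns(traits: TraitTable) -> list[tuple[str, np.ndarray]]:
    """Trait columns as raw arrays: ('quant', x) or ('nominal', indicators)."""
    out: list[tuple[str, np.ndarray]] = []
    for name in traits.trait_names:
        col = traits.traits[name]
        if traits.variable_spec[name]["kind"] == "continuous":
            out.append(("quant", pd.to_numeric(col).to_numpy(dtype=float)))
        else:
            x = col.astype(str).to_numpy()
            levels = pd.unique(x)
            ind = np.column_stack([(x == lv).astype(float) for lv in levels])
            out.append(("nominal", ind))
    return out


def _standardize_raw(raw, w: np.ndarray,
                     perm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hill-Smith transform of permuted raw columns under fixed weights."""
    blocks = []
    metrics = []
    for kind, arr in raw:
        a = arr[perm]
        if kind == "quant":
            mean = w @ a
            ac = a - mean
            sd = np.sqrt(w @ ac**2)
            if sd <= 0:
                raise ValueError("zero weighted variance under permutation")
            blocks.append((ac / sd)[:, None])
            metrics.append(np.array([1.0]))
        else:
            p_m = w @ a
            keep = p_m > 0
            blocks.append(a[:, keep] / p_m[keep][None, :] - 1.0)
            metrics.append(p_m[keep])
    return np.hstack(blocks), np.concatenate(metrics)


def sequential_combine(p_model2: float, p_model4: float) -> float:
    """Combined sequential p: reject only when both component tests reject."""
    for p in (p_model2, p_model4):
        if not (0 < p <= 1):
            raise ValueError(f"p-value out of range: {p}")
    return max(p_model2, p_model4)
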