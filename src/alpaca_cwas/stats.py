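"""Connectome-wide association statistics.

For each edge, connectivity (Fisher-z) is regressed on age, sex, and the
behavioral covariate with ordinary least squares,

    z_e ~ 1 + age + sex + cbcl [+ age:sex],

and two-sided t-tests give per-coefficient p-values. Because edges are
correlated, the family-wise threshold uses the effective number of
independent tests M_eff estimated from the eigenvalue spectrum of the
edge-by-edge correlation matrix, and the Sidak correction

    alpha_corr = 1 - (1 - alpha)^(1 / M_eff),      alpha = 0.05.

The default M_eff estimator sums, over eigenvalues lambda_i of the
inter-edge correlation matrix, an indicator for lambda_i >= 1 plus the
fractional part of lambda_i; it satisfies the boundary identities any
sensible estimator must (independent edges -> M, rank-one correlation -> 1).

Hemispheric symmetry and anatomical-group tallies summarize the significant
edge set: a base region pair (hemisphere stripped) is intrahemispherically
symmetric when its left-left and right-right edges are both significant, and
interhemispherically symmetric when both crossed edges are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .atlas import RegionAtlas


class StatsError(ValueError):
    pass


ASSOCIATION_COLUMNS = [
    "region_a",
    "region_b",
    "beta_age",
    "beta_sex",
    "beta_cbcl",
    "beta_interaction",
    "p_age",
    "p_sex",
    "p_cbcl",
    "p_interaction",
    "n_subjects",
]


def _design(covariates: pd.DataFrame, interaction: bool) -> pd.DataFrame:
    for col in ("age", "sex", "cbcl_sqrt_total"):
        if col not in covariates.columns:
            raise StatsError(f"covariate table missing column {col!r}")
        if covariates[col].isna().any():
            raise StatsError(f"missing values in covariate {col!r}")
    X = pd.DataFrame(
        {
            "age": covariates["age"].to_numpy(float),
            "sex": covariates["sex"].to_numpy(float),
            "cbcl": covariates["cbcl_sqrt_total"].to_numpy(float),
        }
    )
    if interaction:
        X["age_x_sex"] = X["age"] * X["sex"]
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(Xc.drop(columns=[c]).to_numpy())
            == np.linalg.matrix_rank(Xc.to_numpy())
        ]
        raise StatsError(f"collinear covariates: {bad}")
    return Xc


def fit_edge_model(
    z_values: np.ndarray,
    covariates: pd.DataFrame,
    interaction: bool = False,
) -> dict[str, float]:
    """OLS fit of one edge's Fisher-z values on the covariates.

    Returns a row dict with coefficients and two-sided p-values. A constant
    edge (zero variance across subjects) yields a degenerate fit: betas 0,
    p-values 1, with a warning.
    """
    z = np.asarray(z_values, dtype=float)
    X = _design(covariates, interaction)
    n, k = X.shape
    if len(z) != n:
        raise StatsError("edge vector length does not match covariate table")
    if n <= k + 1:
        raise StatsError(f"need more than {k + 1} subjects for a {k}-term model")
    row: dict[str, float] = {
        "beta_age": 0.0,
        "beta_sex": 0.0,
        "beta_cbcl": 0.0,
        "beta_interaction": np.nan,
        "p_age": 1.0,
        "p_sex": 1.0,
        "p_cbcl": 1.0,
        "p_interaction": np.nan,
        "n_subjects": n,
    }
    if np.ptp(z) == 0:
        warnings.warn("constant edge across subjects; degenerate fit", RuntimeWarning)
        if interaction:
            row["beta_interaction"] = 0.0
            row["p_interaction"] = 1.0
        return row
    fit = sm.OLS(z, X).fit()
    row.update(
        beta_age=float(fit.params["age"]),
        beta_sex=float(fit.params["sex"]),
        beta_cbcl=float(fit.params["cbcl"]),
        p_age=float(fit.pvalues["age"]),
        p_sex=float(fit.pvalues["sex"]),
        p_cbcl=float(fit.pvalues["cbcl"]),
    )
    if interaction:
        row["beta_interaction"] = float(fit.params["age_x_sex"])
        row["p_interaction"] = float(fit.pvalues["age_x_sex"])
    return row


def fit_all_edges(
    edge_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    interaction: bool = False,
) -> pd.DataFrame:
    """Edgewise association table over a subjects-by-edges Fisher-z matrix.

    ``edge_matrix`` columns are (region_a, region_b) tuples (or a
    MultiIndex); rows align with ``covariates`` rows.
    """
    rows = []
    for edge in edge_matrix.columns:
        row = fit_edge_model(edge_matrix[edge].to_numpy(), covariates, interaction)
        row["region_a"], row["region_b"] = edge
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


@dataclass(frozen=True)
class CorrectionResult:
    method: str
    M: int
    M_eff: float
    alpha: float
    alpha_corr: float

    def __post_init__(self) -> None:
        if not 1 <= self.M_eff <= self.M:
            raise StatsError("M_eff must lie in [1, M]")
        if not 0 < self.alpha_corr <= self.alpha:
            raise StatsError("alpha_corr must lie in (0, alpha]")


def effective_tests(edge_matrix: np.ndarray, estimator: str = "fractional") -> float:
    """Effective number of independent tests from the inter-edge correlation.

    Eigenvalues lambda of the edges-by-edges Pearson correlation matrix are
    combined as

        fractional (default):  M_eff = sum_i [ I(lambda_i >= 1)
                                               + (lambda_i - floor(lambda_i)) ]
        kaiser:                M_eff = #{ lambda_i >= 1 }

    Both reduce to M for independent edges and to 1 for a rank-one
    correlation matrix. The result is clamped to [1, M].
    """
    X = np.asarray(edge_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise StatsError("need a subjects-by-edges matrix with >= 2 edges")
    if X.shape[0] < 3:
        raise StatsError("need >= 3 subjects to estimate the edge correlation")
    if np.any(X.std(axis=0) == 0):
        raise StatsError("zero-variance edge in the correlation matrix input")
    corr = np.corrcoef(X, rowvar=False)
    return effective_tests_from_correlation(corr, estimator)


def effective_tests_from_correlation(
    corr: np.ndarray, estimator: str = "fractional"
) -> float:
    corr = np.asarray(corr, dtype=float)
    m = corr.shape[0]
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)  # guard tiny negative round-off
    # round-off guard: the floor/indicator terms are discontinuous at integer
    # eigenvalues (e.g. a rank-one matrix with lambda = M - 1e-12)
    lam = np.round(lam, 8)
    if estimator == "fractional":
        m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    elif estimator == "kaiser":
        m_eff = float(np.sum(lam >= 1))
    else:
        raise StatsError(f"unknown M_eff estimator {estimator!r}")
    return float(np.clip(m_eff, 1.0, m))


def sidak_alpha(m_eff: float, alpha: float = 0.05) -> float:
    """Sidak-corrected per-test threshold for M_eff effective tests."""
    if m_eff < 1:
        raise StatsError("M_eff must be >= 1")
    return float(1.0 - (1.0 - alpha) ** (1.0 / m_eff))


def correct(
    edge_matrix: np.ndarray,
    method: str,
    alpha: float = 0.05,
    estimator: str = "fractional",
) -> CorrectionResult:
    m = np.asarray(edge_matrix).shape[1]
    m_eff = effective_tests(edge_matrix, estimator)
    return CorrectionResult(
        method=method, M=m, M_eff=m_eff, alpha=alpha, alpha_corr=sidak_alpha(m_eff, alpha)
    )


def significant_edges(
    table: pd.DataFrame,
    correction: CorrectionResult,
    covariate: str = "age",
) -> pd.DataFrame:
    """Edges whose p-value for ``covariate`` clears the corrected threshold.

    Returns a frame (region_a, region_b, beta, p, sign) with sign = +/-1.
    """
    if covariate not in ("age", "sex", "interaction"):
        raise StatsError(f"unknown covariate {covariate!r}")
    pcol, bcol = f"p_{covariate}", f"beta_{covariate}"
    sig = table[table[pcol] < correction.alpha_corr].copy()
    out = pd.DataFrame(
        {
            "region_a": sig["region_a"],
            "region_b": sig["region_b"],
            "beta": sig[bcol],
            "p": sig[pcol],
            "sign": np.sign(sig[bcol]).astype(int),
        }
    ).reset_index(drop=True)
    return out


def _split_key(key: str) -> tuple[str, str]:
    base, hemi = key.rsplit("_", 1)
    return base, hemi


def classify_symmetry(sig: pd.DataFrame, atlas: RegionAtlas) -> pd.DataFrame:
    """Hemispheric-symmetry flags per hemisphere-stripped base region pair.

    intra_symmetric: X_L-Y_L and X_R-Y_R both significant;
    inter_symmetric: X_L-Y_R and X_R-Y_L both significant.
    Only base pairs with at least one flag set are returned.
    """
    edges = {
        frozenset((a, b))
        for a, b in zip(sig["region_a"], sig["region_b"])
    }
    base_pairs = set()
    for a, b in zip(sig["region_a"], sig["region_b"]):
        base_pairs.add(frozenset((_split_key(a)[0], _split_key(b)[0])))
    rows = []
    for pair in sorted(base_pairs, key=sorted):
        members = sorted(pair)
        x = members[0]
        y = members[-1]  # same as x for self-pairs (X_L - X_R)
        intra = (
            frozenset((f"{x}_L", f"{y}_L")) in edges
            and frozenset((f"{x}_R", f"{y}_R")) in edges
        )
        inter = (
            frozenset((f"{x}_L", f"{y}_R")) in edges
            and frozenset((f"{x}_R", f"{y}_L")) in edges
        )
        if intra or inter:
            rows.append(
                {
                    "region_x": x,
                    "region_y": y,
                    "intra_symmetric": intra,
                    "inter_symmetric": inter,
                }
            )
    return pd.DataFrame(
        rows, columns=["region_x", "region_y", "intra_symmetric", "inter_symmetric"]
    )


def tally_by_group(sig: pd.DataFrame, atlas: RegionAtlas) -> pd.DataFrame:
    """Count significant edges by (group pair, sign, hemispheric location).

    Location is Left (both regions left), Right (both right) or Between
    (opposite hemispheres). Group pairs are order-insensitive and rendered
    alphabetically, e.g. ``Fro/Sub``. Cell counts partition the significant
    set exactly.
    """
    rows = []
    for _, edge in sig.iterrows():
        ra = atlas.region(edge["region_a"])
        rb = atlas.region(edge["region_b"])
        gpair = "/".join(sorted([ra.group, rb.group]))
        if ra.hemisphere == rb.hemisphere:
            location = "Left" if ra.hemisphere == "L" else "Right"
        else:
            location = "Between"
        rows.append(
            {
                "group_pair": gpair,
                "sign": "positive" if edge["sign"] > 0 else "negative",
                "location": location,
            }
        )
    counted = (
        pd.DataFrame(rows, columns=["group_pair", "sign", "location"])
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["group_pair", "sign", "location"])
        .reset_index(drop=True)
    )
    return counted


def edge_matrix_from_connectomes(connectomes: Sequence) -> pd.DataFrame:
    """Stack per-subject connectomes into a subjects-by-edges z matrix.

    Edges that are missing (degenerate) in any subject are dropped so they
    inflate neither M nor M_eff.
    """
    series = [c.edge_series() for c in connectomes]
    df = pd.DataFrame(series).reset_index(drop=True)
    good = df.columns[df.notna().all(axis=0)]
    return df[good]
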