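"""Per-group PCA, loading-threshold marker selection and differential correlations.

The marker matrix of one group (control or immunized), standardized per
variable, is decomposed by SVD.  Markers whose Pearson correlation with a
component score exceeds 0.8 in magnitude form that component's cluster; the
clusters of the first ("governing") component of the control group define
the signature markers whose pairwise correlation structure is then compared
between groups.  Each marker pair is classified by how immunization changed
its correlation: retained, inverted, lost, gained or neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from immunosig.panels import StandardizedMatrix


@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray  # variables × components, orthonormal columns
    eigenvalues: np.ndarray  # descending, non-negative
    scores: np.ndarray  # samples × components
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class MarkerSelection:
    group: str
    component_scope: str  # "first_component" | "first_four"
    threshold: float
    selected: list[tuple[str, int, float]]  # (variable, component index, r)

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for variable, _, _ in self.selected:
            if variable not in seen:
                seen.append(variable)
        return seen


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray  # symmetric, unit diagonal; NaN marks undefined entries


@dataclass
class SignatureTable:
    rows: list[tuple[tuple[str, str], float, float, str]]
    # ((marker_a, marker_b), r_control, r_immunized, class)

    def classes(self) -> dict[tuple[str, str], str]:
        return {pair: cls for pair, _, _, cls in self.rows}


def pca(std_matrix: StandardizedMatrix) -> PCAResult:
    """SVD-based PCA of a standardized matrix (sample, n−1 normalization).

    Component signs are fixed so the largest-magnitude loading of each
    component is positive.  With p variables and n samples at most
    min(n−1, p) components carry positive eigenvalue; the rest are dropped
    with a rank-deficiency warning when p ≥ n.
    """
    X = std_matrix.values
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig[0], 1.0) * 1e-12 if eig.size else np.array([], bool)
    if p >= n or int(keep.sum()) < min(n - 1, p):
        warnings.warn(
            f"rank deficiency: {p} variables, {n} samples, "
            f"{int(keep.sum())} components retained",
            stacklevel=2,
        )
    U, s, Vt, eig = U[:, keep], s[keep], Vt[keep], eig[keep]
    loadings = Vt.T
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = U * s * signs
    return PCAResult(
        variables=list(std_matrix.variables),
        loadings=loadings,
        eigenvalues=eig,
        scores=scores,
        variance_fraction=eig / eig.sum(),
    )


def variance_explained(result: PCAResult, k: int = 4) -> float:
    """Cumulative variance fraction of the first k components.

    Warns when the conventional 80% criterion for the first four
    components is not met.
    """
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k={k} out of range 1..{result.n_components}")
    frac = float(result.variance_fraction[:k].sum())
    if k == 4 and frac <= 0.8:
        warnings.warn(f"first 4 components explain only {frac:.1%} of variance",
                      stacklevel=2)
    return frac


def marker_component_correlations(result: PCAResult,
                                  std_matrix: StandardizedMatrix) -> np.ndarray:
    """Pearson r between each standardized variable and each component score.

    On standardized data this equals loading_jk · sqrt(eigenvalue_k) up to
    the sample-SD normalization of the variable.
    """
    X = std_matrix.values
    if X.shape[0] != result.scores.shape[0]:
        raise ValueError("matrix and scores have different sample counts")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Sc = result.scores - result.scores.mean(axis=0)
    x_sd = Xc.std(axis=0, ddof=1)
    s_sd = Sc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Sc) / (n - 1) / np.outer(x_sd, s_sd)
    r[:, s_sd == 0] = np.nan
    return r


def select_markers(corr_matrix: np.ndarray, variables: list[str],
                   group: str = "control", scope: str = "first_component",
                   threshold: float = 0.8) -> MarkerSelection:
    """Markers strictly exceeding |r| > threshold against the scoped components.

    ``scope`` limits the search to the governing component (PC1) or the
    first four components.  An empty selection is allowed (with a warning).
    """
    if scope == "first_component":
        cols = range(min(1, corr_matrix.shape[1]))
    elif scope == "first_four":
        cols = range(min(4, corr_matrix.shape[1]))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    selected = []
    for k in cols:
        for j, variable in enumerate(variables):
            r = corr_matrix[j, k]
            if np.isfinite(r) and abs(r) > threshold:
                selected.append((variable, k, float(r)))
    if not selected:
        warnings.warn(f"no marker exceeds |r| > {threshold} for scope {scope}",
                      stacklevel=2)
    return MarkerSelection(group=group, component_scope=scope,
                           threshold=threshold, selected=selected)


def correlation_heatmap(values: np.ndarray, markers: list[str]) -> CorrelationMatrix:
    """Pairwise Pearson correlations among markers within one group's rows.

    Constant markers yield NaN off-diagonal entries (flagged undefined);
    the diagonal is exactly 1.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    if X.shape[1] != len(markers):
        raise ValueError("marker list does not match column count")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(variables=list(markers), r=r)


def compare_signatures(ctrl: CorrelationMatrix, imm: CorrelationMatrix,
                       neutral_band: float = 0.2,
                       strong: float = 0.5) -> SignatureTable:
    """Classify each marker pair by how its correlation changed with immunization.

    neutral — both |r| below the neutral band; inverted — sign flip with
    both |r| at or above the band; lost — strong in control, neutral in
    immunized; gained — the mirror; retained — everything else.
    """
    if ctrl.variables != imm.variables:
        raise ValueError("marker sets differ between the two groups")
    rows = []
    p = len(ctrl.variables)
    for i in range(p):
        for j in range(i + 1, p):
            rc, ri = float(ctrl.r[i, j]), float(imm.r[i, j])
            pair = (ctrl.variables[i], ctrl.variables[j])
            if not (np.isfinite(rc) and np.isfinite(ri)):
                rows.append((pair, rc, ri, "undefined"))
                continue
            if abs(rc) < neutral_band and abs(ri) < neutral_band:
                cls = "neutral"
            elif np.sign(rc) != np.sign(ri) and abs(rc) >= neutral_band and abs(ri) >= neutral_band:
                cls = "inverted"
            elif abs(rc) >= strong and abs(ri) < neutral_band:
                cls = "lost"
            elif abs(ri) >= strong and abs(rc) < neutral_band:
                cls = "gained"
            else:
                cls = "retained"
            rows.append((pair, rc, ri, cls))
    return SignatureTable(rows=rows)


def group_signature_analysis(std_ctrl: StandardizedMatrix, std_imm: StandardizedMatrix,
                             threshold: float = 0.8, neutral_band: float = 0.2,
                             strong: float = 0.5):
    """Full per-tissue signature workflow.

    PCA per group, selection of the control group's governing-component
    markers, per-group correlation heat-maps restricted to those markers,
    and the differential classification table.  Returns
    (control selection, immunized selection, control heatmap, immunized
    heatmap, signature table).
    """
    res_c = pca(std_ctrl)
    res_i = pca(std_imm)
    corr_c = marker_component_correlations(res_c, std_ctrl)
    corr_i = marker_component_correlations(res_i, std_imm)
    sel_c = select_markers(corr_c, std_ctrl.variables, "control", "first_component", threshold)
    sel_i = select_markers(corr_i, std_imm.variables, "immunized", "first_component", threshold)
    markers = sel_c.markers
    if not markers:
        return sel_c, sel_i, None, None, SignatureTable(rows=[])
    idx = [std_ctrl.variables.index(m) for m in markers]
    heat_c = correlation_heatmap(std_ctrl.values[:, idx], markers)
    heat_i = correlation_heatmap(std_imm.values[:, idx], markers)
    table = compare_signatures(heat_c, heat_i, neutral_band, strong)
    return sel_c, sel_i, heat_c, heat_i, table
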