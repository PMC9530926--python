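"""Group dichotomization and sparse PLS discriminant analysis (sPLS-DA).

Subjects are split into two groups either by an audiological threshold
(mean hearing level above 29 dB HL, or mean DPOAE level below 16 dB EPL;
boundary values fall in the normal group) or by DNA-repair genotype
pooling.  sPLS-DA then finds, per component, a linear combination of at
most ``keep`` variables that maximizes covariance with the group label:
classic NIPALS PLS weight vectors hard-thresholded to their ``keep``
largest-magnitude entries, with deflation of both the data and the label
between components.  Biplot tables expose case scores, variable-score
correlations and the centroid-to-centroid direction of maximal
discrimination, ready for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GroupAssignment", "SplsModel", "dichotomize", "fit_spls_da", "biplot_tables"]

HL_IMPAIRED_ABOVE = 29.0  # dB HL, mean over the audiometric grid
DPOAE_IMPAIRED_BELOW = 16.0  # dB EPL, mean over the third-octave bands


@dataclass
class GroupAssignment:
    subject: str
    basis: str  # HL_mean | DPOAE_mean | hOGG1 | XRCC1
    label: str
    threshold: float | None = None


@dataclass
class SplsModel:
    n_components: int
    keep: int
    loadings: pd.DataFrame  # variables x components, <= keep nonzero each
    scores: pd.DataFrame  # subjects x components
    direction: np.ndarray  # unit vector, group A centroid -> group B centroid
    variable_correlations: pd.DataFrame  # variables x components
    labels: pd.Series
    groups: tuple[str, str]
    means: pd.Series
    scales: pd.Series


def dichotomize(
    hl: pd.DataFrame | None = None,
    dpoae: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
    basis: str = "HL_mean",
) -> list[GroupAssignment]:
    """Assign each subject to one of two groups.

    ``HL_mean``: impaired iff mean HL strictly above 29 dB HL.
    ``DPOAE_mean``: impaired iff mean DPOAE strictly below 16 dB EPL.
    ``hOGG1``: wt vs {mut, het}.  ``XRCC1``: {wt, mut} vs het.
    """
    out: list[GroupAssignment] = []
    if basis == "HL_mean":
        if hl is None:
            raise ValueError("HL table required for HL_mean basis")
        _check_complete(hl, "HL")
        for subj, row in hl.iterrows():
            label = "impaired" if row.mean() > HL_IMPAIRED_ABOVE else "normal"
            out.append(GroupAssignment(str(subj), basis, label, HL_IMPAIRED_ABOVE))
    elif basis == "DPOAE_mean":
        if dpoae is None:
            raise ValueError("DPOAE table required for DPOAE_mean basis")
        _check_complete(dpoae, "DPOAE")
        for subj, row in dpoae.iterrows():
            label = "impaired" if row.mean() < DPOAE_IMPAIRED_BELOW else "normal"
            out.append(GroupAssignment(str(subj), basis, label, DPOAE_IMPAIRED_BELOW))
    elif basis in ("hOGG1", "XRCC1"):
        if cohort is None:
            raise ValueError("cohort table required for genotype bases")
        group_a = {"wt"} if basis == "hOGG1" else {"wt", "mut"}
        for subj, row in cohort.iterrows():
            label = "groupA" if row[basis] in group_a else "groupB"
            out.append(GroupAssignment(str(subj), basis, label, float("nan")))
    else:
        raise ValueError(f"unknown basis {basis!r}")
    labels = {a.label for a in out}
    if len(labels) < 2:
        warnings.warn(
            f"dichotomization on {basis} produced a single group ({labels.pop()})",
            stacklevel=2,
        )
    return out


def _check_complete(table: pd.DataFrame, name: str) -> None:
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(f"missing {name} audiology for subject(s): {bad}")


def assignments_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [a.subject for a in assignments],
            "basis": [a.basis for a in assignments],
            "label": [a.label for a in assignments],
            "threshold": [a.threshold for a in assignments],
        }
    ).set_index("subject")


def fit_spls_da(
    X: pd.DataFrame,
    labels: pd.Series | list[str],
    n_components: int = 2,
    keep: int = 5,
    scale: bool = True,
) -> SplsModel:
    """Sparse PLS-DA of a subjects x variables matrix against two groups.

    Variables are centered (and unit-scaled unless ``scale=False``); the
    class label is coded +1/-1.  Per component the PLS weight vector
    (cross-covariance with the current label residual) is hard-thresholded
    to its ``keep`` top-magnitude entries and unit-normalized, with the
    sign convention that the largest-|weight| entry is positive; scores are
    the deflated data projected on the weights.  With ``keep`` equal to the
    number of variables this reduces to classical PLS-DA.
    """
    labels = pd.Series(labels, index=X.index if not isinstance(labels, pd.Series) else None)
    if isinstance(labels.index, pd.RangeIndex) and not isinstance(X.index, pd.RangeIndex):
        labels.index = X.index
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 groups, found {classes}")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"each group needs at least 2 subjects: {sizes.to_dict()}")
    if keep > X.shape[1]:
        raise ValueError("keep exceeds the number of variables")

    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1) if scale else pd.Series(1.0, index=X.columns)
    scales = scales.replace(0.0, 1.0)  # constant columns carry no signal
    Z = ((X - means) / scales).to_numpy(dtype=float)
    y = np.where(labels.to_numpy() == classes[1], 1.0, -1.0)
    y = y - y.mean()

    n, p = Z.shape
    Zh, yh = Z.copy(), y.copy()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    for h in range(n_components):
        w = Zh.T @ yh
        if np.allclose(w, 0):
            break
        order = np.argsort(np.abs(w))
        w[order[: p - keep]] = 0.0
        w /= np.linalg.norm(w)
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Zh @ w
        tt = float(t @ t)
        Zh = Zh - np.outer(t, (Zh.T @ t) / tt)
        yh = yh - t * float(yh @ t) / tt
        W[:, h], T[:, h] = w, t

    comp_names = [f"comp{h + 1}" for h in range(n_components)]
    scores = pd.DataFrame(T, index=X.index, columns=comp_names)
    loadings = pd.DataFrame(W, index=X.columns, columns=comp_names)

    cent_a = scores[labels == classes[0]].mean(axis=0).to_numpy()
    cent_b = scores[labels == classes[1]].mean(axis=0).to_numpy()
    delta = cent_b - cent_a
    norm = np.linalg.norm(delta)
    direction = delta / norm if norm > 0 else delta

    corr = np.zeros((p, n_components))
    for h in range(n_components):
        t = T[:, h]
        st = t.std(ddof=1)
        for j in range(p):
            sj = Z[:, j].std(ddof=1)
            if st > 0 and sj > 0:
                corr[j, h] = float(np.corrcoef(Z[:, j], t)[0, 1])
    variable_correlations = pd.DataFrame(corr, index=X.columns, columns=comp_names)

    return SplsModel(
        n_components=n_components,
        keep=keep,
        loadings=loadings,
        scores=scores,
        direction=direction,
        variable_correlations=variable_correlations,
        labels=labels,
        groups=(str(classes[0]), str(classes[1])),
        means=means,
        scales=scales,
    )


def biplot_tables(
    model: SplsModel, corr_cutoff: float = 0.75
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Plot-ready tables: case coordinates, variable arrows, direction.

    Variable arrows are the correlations of each variable with the first
    two score axes, kept when the arrow length (Euclidean norm of the two
    correlations) exceeds ``corr_cutoff``; the direction is the unit vector
    from the first group's centroid to the second's in score space.
    """
    if model.n_components < 2:
        raise ValueError("biplot needs at least 2 components")
    cases = model.scores.iloc[:, :2].copy()
    cases["label"] = model.labels.values
    vc = model.variable_correlations.iloc[:, :2]
    length = np.sqrt((vc**2).sum(axis=1))
    arrows = vc[length > corr_cutoff].copy()
    return cases, arrows, model.direction[:2]
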