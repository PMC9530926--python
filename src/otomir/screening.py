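"""Correlation screening of microRNAs against audiological band levels.

A microRNA is flagged as associated with auditory function when its
log2-transformed normalized expression correlates (|Pearson r| strictly
greater than a threshold, default 0.3) with the outcome level in at least
``min_bands`` (default 3) frequency bands.  The filter runs independently
for hearing level (11 audiometric frequencies) and DPOAE level (third-octave
bands); the union of selections carries an outcome label.  No multiplicity
correction is applied at this stage; it is a screening heuristic whose
operating characteristics at small n are quantified by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenResult", "correlation_matrix", "screen_mirnas", "screen_table"]


@dataclass
class ScreenResult:
    mirna: str
    outcome: str  # HL | DPOAE
    correlations: dict[str, float]
    n_bands_passing: int
    selected: bool
    dominant_sign: str  # positive | negative | mixed

    def __post_init__(self) -> None:
        assert self.selected == (self.n_bands_passing >= self._min_bands)

    _min_bands: int = field(default=3, repr=False)


def correlation_matrix(norm_counts: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between log2(normalized count + 1) and each outcome band.

    ``norm_counts``: genes x subjects normalized expression;
    ``outcomes``: subjects x bands levels.  Constant columns (either side)
    yield r = 0 so they can never pass the screen.
    """
    if set(norm_counts.columns) != set(outcomes.index):
        raise ValueError("subject sets of counts and outcomes differ")
    if outcomes.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation screen")
    x = np.log2(norm_counts.loc[:, outcomes.index].to_numpy(dtype=float) + 1.0)
    y = outcomes.to_numpy(dtype=float)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / np.outer(sx, sy)
    r = np.where(np.isfinite(r), r, 0.0)
    return pd.DataFrame(r, index=norm_counts.index, columns=outcomes.columns)


def screen_mirnas(
    correlations: pd.DataFrame,
    outcome: str,
    threshold: float = 0.3,
    min_bands: int = 3,
) -> list[ScreenResult]:
    """Apply the band-count filter to a (mirna x band) correlation table.

    Selection requires strictly |r| > threshold in at least ``min_bands``
    bands; |r| exactly at the threshold never counts.
    """
    if min_bands > correlations.shape[1]:
        raise ValueError("min_bands exceeds the number of bands")
    out: list[ScreenResult] = []
    for mirna, row in correlations.iterrows():
        passing = row[row.abs() > threshold]
        n_pass = int(len(passing))
        if n_pass and (passing > 0).all():
            sign = "positive"
        elif n_pass and (passing < 0).all():
            sign = "negative"
        else:  # no passing bands, or passing signs disagree
            sign = "mixed"
        out.append(
            ScreenResult(
                mirna=str(mirna),
                outcome=outcome,
                correlations=row.to_dict(),
                n_bands_passing=n_pass,
                selected=n_pass >= min_bands,
                dominant_sign=sign,
                _min_bands=min_bands,
            )
        )
    return out


def screen_table(
    norm_counts: pd.DataFrame,
    hl: pd.DataFrame,
    dpoae: pd.DataFrame,
    threshold: float = 0.3,
    min_bands: int = 3,
) -> pd.DataFrame:
    """Run the screen against HL and DPOAE and report the union.

    One row per (mirna, outcome); ``selected`` marks survivors.  Per-band
    correlations are included as extra columns prefixed ``r_``.
    """
    frames = []
    for outcome, table in (("HL", hl), ("DPOAE", dpoae)):
        corr = correlation_matrix(norm_counts, table)
        results = screen_mirnas(corr, outcome, threshold=threshold, min_bands=min_bands)
        rows = []
        for res in results:
            row = {
                "mirna": res.mirna,
                "outcome": res.outcome,
                "n_bands_passing": res.n_bands_passing,
                "selected": res.selected,
                "dominant_sign": res.dominant_sign,
            }
            row.update({f"r_{band}": r for band, r in res.correlations.items()})
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
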