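"""RPKM-to-fold-change conversion and multi-omic matrix fusion.

Transcript abundances (RPKM) are converted to fold changes centered
around 1 by dividing each condition column by the mean of the standard
control replicates. Flux matrices are converted the same way against
the standard-control row, with an explicit policy for the degenerate
ratios (0/0, x/0) that arise when reactions are silent in the control.
Transcript and flux fold changes are finally concatenated column-wise
into one conditions x features matrix with an appended all-ones row
representing the standard control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "rpkm_to_foldchange",
    "flux_foldchange",
    "build_multiomic",
    "subset_growth_conditions",
]

logger = logging.getLogger(__name__)


@dataclass
class OmicsMatrix:
    """Conditions x features table with per-feature kind/metadata tags."""

    values: pd.DataFrame
    feature_kind: pd.Series  # per column: 'transcript' or 'flux'
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.feature_kind.index) != list(self.values.columns):
            raise ValueError("feature_kind index must match matrix columns")

    @property
    def condition_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


def rpkm_to_foldchange(
    rpkm: pd.DataFrame,
    control_columns: Sequence[str],
    condition_columns: Sequence[str],
) -> pd.DataFrame:
    """Divide condition RPKM columns by the mean of control replicates.

    Genes expressed at control-like levels map to fold changes near 1.
    Genes whose control mean is zero yield non-finite ratios; these are
    left in place here and resolved by the downstream fusion policy.
    """
    if len(control_columns) < 1:
        raise ValueError("at least one control replicate column is required")
    ctrl = rpkm[list(control_columns)].astype(float)
    cond = rpkm[list(condition_columns)].astype(float)
    if (ctrl.to_numpy() < 0).any() or (cond.to_numpy() < 0).any():
        raise ValueError("RPKM values must be non-negative")
    mean_ctrl = ctrl.mean(axis=1)
    n_zero = int((mean_ctrl == 0).sum())
    if n_zero:
        logger.warning(
            "%d genes have zero control mean; their fold changes are non-finite "
            "until the fusion policy is applied",
            n_zero,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = cond.div(mean_ctrl, axis=0)
    return fc


def flux_foldchange(
    flux: pd.DataFrame,
    control_row: str | int = -1,
    threshold: float = 1e-4,
) -> pd.DataFrame:
    """Flux fold changes against the standard-control row.

    Policy, in order: (a) the maximum finite fold change of the matrix
    is found treating Inf as 0 and ignoring NaN; (b) ratios are
    recomputed; (c) values <= ``threshold`` are zeroed; (d) NaN (0/0,
    silent in both condition and control) becomes 1; (e) Inf (active in
    the condition, silent in the control) becomes the value from (a).
    """
    if isinstance(control_row, int):
        try:
            control_label = flux.index[control_row]
        except IndexError as exc:
            raise IndexError(
                f"control row index {control_row} out of range for "
                f"{len(flux.index)} conditions"
            ) from exc
    else:
        if control_row not in flux.index:
            raise KeyError(f"control row {control_row!r} not in flux matrix")
        control_label = control_row

    ctrl = flux.loc[control_label].astype(float)
    others = flux.drop(index=control_label).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = others.div(ctrl, axis=1).to_numpy()

    finite_scan = fc.copy()
    finite_scan[np.isinf(finite_scan)] = 0.0
    finite_vals = finite_scan[~np.isnan(finite_scan)]
    max_fc = float(finite_vals.max()) if finite_vals.size else 0.0

    with np.errstate(invalid="ignore"):
        fc[fc <= threshold] = 0.0  # NaN/Inf compare False and survive
    fc[np.isnan(fc)] = 1.0
    fc[np.isinf(fc)] = max_fc
    return pd.DataFrame(fc, index=others.index, columns=others.columns)


def build_multiomic(
    transcript_fc: pd.DataFrame,
    flux_fc: pd.DataFrame,
    control_name: str = "Standardcontrol",
    transcript_meta: pd.DataFrame | None = None,
    flux_meta: pd.DataFrame | None = None,
) -> OmicsMatrix:
    """Concatenate transcript and flux fold changes; append the control row.

    Both inputs must list the same conditions in the same order. The
    appended final row of all ones represents the standard control fold
    change.
    """
    if list(transcript_fc.index) != list(flux_fc.index):
        raise ValueError("transcript and flux condition rows must match in order")
    merged = pd.concat([transcript_fc, flux_fc], axis=1)
    control = pd.DataFrame(
        np.ones((1, merged.shape[1])), index=[control_name], columns=merged.columns
    )
    values = pd.concat([merged, control])
    kind = pd.Series(
        ["transcript"] * transcript_fc.shape[1] + ["flux"] * flux_fc.shape[1],
        index=values.columns,
    )
    meta = None
    if transcript_meta is not None or flux_meta is not None:
        parts = [m for m in (transcript_meta, flux_meta) if m is not None]
        meta = pd.concat(parts)
    arr = values.to_numpy()
    if np.isinf(arr).any() or np.isnan(arr).any():
        raise ValueError("fused matrix contains Inf/NaN; apply the fold-change policy first")
    return OmicsMatrix(values=values, feature_kind=kind, feature_meta=meta)


def subset_growth_conditions(
    matrix: OmicsMatrix | pd.DataFrame,
    available: Sequence[str],
    growth_rates: Sequence[float],
    control_name: str = "Standardcontrol",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict a conditions x features matrix to conditions with growth rates.

    Retained rows are the standard control followed by ``available`` in
    the given order; ``growth_rates`` aligns row-for-row (control
    first). Matrices that lack a control row (e.g. transcript-only fold
    changes) get a synthesized all-ones control row, since the control's
    fold change against itself is 1 everywhere.
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    if len(growth_rates) != len(available) + 1:
        raise ValueError(
            f"growth-rate vector length {len(growth_rates)} != "
            f"1 (control) + {len(available)} available conditions"
        )
    missing = [c for c in available if c not in values.index]
    if missing:
        raise KeyError(f"conditions {missing} not present in the matrix")
    if control_name in values.index:
        control = values.loc[[control_name]]
    else:
        control = pd.DataFrame(
            np.ones((1, values.shape[1])), index=[control_name], columns=values.columns
        )
    subset = pd.concat([control, values.loc[list(available)]])
    return subset, np.asarray(growth_rates, dtype=float)
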