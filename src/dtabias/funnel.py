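"""Funnel-plot coordinates and rendering for the supported axis catalogue.

Horizontal axes: lnDOR, DOR, sensitivity, specificity.  Vertical axes:
SE(lnDOR), 1/Var(lnDOR), 1/sqrt(ESS), total sample size, and the
(inverse) binomial standard error of the plotted accuracy fraction.
SE-like axes are drawn inverted so the funnel opens downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .effects import study_effect
from .exceptions import CatalogueError, DegenerateEffectError, RenderError
from .study_data import MetaAnalysis, StudyTable

__all__ = ["FunnelSpec", "FunnelData", "funnel_coordinates", "render_funnel"]

X_AXES = ("ln_dor", "dor", "sensitivity", "specificity")
Y_AXES = (
    "se_ln_dor",
    "inv_var_ln_dor",
    "inv_sqrt_ess",
    "sample_size",
    "se_of_x",
    "inv_se_of_x",
)
# se_of_x / inv_se_of_x need a well-defined SE for the x quantity.
_SE_OF_X_SUPPORTED = ("sensitivity", "specificity", "ln_dor")
# axes where small values mean high precision -> drawn inverted
_INVERTED_Y = ("se_ln_dor", "inv_sqrt_ess", "se_of_x")


@dataclass(frozen=True)
class FunnelSpec:
    """One axis convention from the supported catalogue."""

    x_axis: str = "ln_dor"
    y_axis: str = "inv_sqrt_ess"
    y_inverted: bool | None = None

    def __post_init__(self) -> None:
        if self.x_axis not in X_AXES or self.y_axis not in Y_AXES:
            raise CatalogueError(
                f"unsupported axis pair ({self.x_axis!r}, {self.y_axis!r}); "
                f"supported: x in {X_AXES}, y in {Y_AXES}"
            )
        if self.y_axis in ("se_of_x", "inv_se_of_x") and self.x_axis not in _SE_OF_X_SUPPORTED:
            raise CatalogueError(
                f"y-axis {self.y_axis!r} requires x in {_SE_OF_X_SUPPORTED}"
            )
        if self.y_inverted is None:
            object.__setattr__(self, "y_inverted", self.y_axis in _INVERTED_Y)


@dataclass(frozen=True)
class FunnelData:
    meta_id: str
    points: tuple[tuple[float, float, str], ...]  # (x, y, study_id)
    spec: FunnelSpec
    excluded: tuple[tuple[str, str], ...] = ()  # (study_id, reason)


def _xy(table: StudyTable, spec: FunnelSpec, continuity: float) -> tuple[float, float]:
    effect = study_effect(table, continuity=continuity)
    n1, n2 = table.n_diseased, table.n_nondiseased

    if spec.x_axis == "ln_dor":
        x = effect.ln_dor
    elif spec.x_axis == "dor":
        x = effect.dor
    elif spec.x_axis == "sensitivity":
        x = table.sensitivity
    else:
        x = table.specificity

    if spec.y_axis == "se_ln_dor":
        y = effect.se_ln_dor
    elif spec.y_axis == "inv_var_ln_dor":
        y = 1.0 / effect.var_ln_dor
    elif spec.y_axis == "inv_sqrt_ess":
        y = effect.inv_sqrt_ess
    elif spec.y_axis == "sample_size":
        y = float(table.n_total)
    else:  # se_of_x / inv_se_of_x
        if spec.x_axis == "ln_dor":
            se = effect.se_ln_dor
        elif spec.x_axis == "sensitivity":
            p = table.sensitivity
            se = math.sqrt(p * (1.0 - p) / n1)
        else:
            p = table.specificity
            se = math.sqrt(p * (1.0 - p) / n2)
        if spec.y_axis == "se_of_x":
            y = se
        else:
            if se == 0.0:
                raise DegenerateEffectError("zero SE: inverse undefined")
            y = 1.0 / se
    return x, y


def funnel_coordinates(
    meta: MetaAnalysis, spec: FunnelSpec | None = None, continuity: float = 0.5
) -> FunnelData:
    """Per-study (x, y) coordinates for the requested axis convention.

    Studies whose coordinates are degenerate (for example a zero cell
    with ``continuity = 0``) are listed in ``excluded`` with a reason.
    """
    spec = spec or FunnelSpec()
    points = []
    excluded = []
    for table in meta.studies:
        try:
            x, y = _xy(table, spec, continuity)
        except DegenerateEffectError as exc:
            excluded.append((table.study_id, str(exc)))
            continue
        if not (math.isfinite(x) and math.isfinite(y)):
            excluded.append((table.study_id, "non-finite coordinate"))
            continue
        points.append((x, y, table.study_id))
    return FunnelData(
        meta_id=meta.meta_id, points=tuple(points), spec=spec, excluded=tuple(excluded)
    )


_AXIS_LABELS = {
    "ln_dor": "lnDOR",
    "dor": "DOR",
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "se_ln_dor": "SE(lnDOR)",
    "inv_var_ln_dor": "1/Var(lnDOR)",
    "inv_sqrt_ess": "1/√ESS",
    "sample_size": "Sample size",
    "se_of_x": "SE",
    "inv_se_of_x": "1/SE",
}


def render_funnel(
    data: FunnelData, path: str, pooled_x: float | None = None
) -> str:
    """Render a funnel scatter to ``path`` (PNG or SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not data.points:
        raise RenderError(f"meta {data.meta_id!r}: no points to draw")
    xs = [p[0] for p in data.points]
    ys = [p[1] for p in data.points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs, ys, s=28, facecolors="none", edgecolors="black")
    if pooled_x is not None:
        ax.axvline(pooled_x, linestyle="--", linewidth=1, color="grey")
    ax.set_xlabel(_AXIS_LABELS[data.spec.x_axis])
    ax.set_ylabel(_AXIS_LABELS[data.spec.y_axis])
    if data.spec.y_inverted:
        ax.invert_yaxis()
    ax.set_title(data.meta_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
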