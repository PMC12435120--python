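"""Figure rendering: limit corridors, baselines and likely bands.

Red = abbreviated-only baseline, blue = full-only baseline, green = the
adaptive corridor (solid limit curves over a light fill) with a darker
band between dotted lines for the likely range.  Duration panels can be
drawn on a percent-of-full-duration axis.  Rendering never mutates the
numeric results; invalid inputs fail before any file is written.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from matplotlib.figure import Figure

from .exceptions import ParameterError
from .model import DURATION_ATOL, PROB_ATOL
from .sweeps import LikelyBand, SweepResult

AXIS_LABELS = {
    "ai_sensitivity": "AI sensitivity",
    "ai_specificity": "AI specificity",
    "rad_sensitivity_abbr": "radiologist sensitivity (abbreviated)",
    "rad_specificity_abbr": "radiologist specificity (abbreviated)",
    "t_full": "full protocol duration [s]",
    "t_abbr": "abbreviated protocol duration [s]",
}


def _check_band(result: SweepResult, band: LikelyBand) -> None:
    if len(band.table) != len(result.table):
        raise ParameterError("band and sweep result have different grid lengths")
    r, b = result.table, band.table
    if not np.allclose(r["value"], b["value"], atol=1e-12):
        raise ParameterError("band and sweep result grids differ")
    rr_ok = (
        (b["rr_band_lower"] >= r["rr_adaptive_lower"] - PROB_ATOL)
        & (b["rr_band_upper"] <= r["rr_adaptive_upper"] + PROB_ATOL)
    ).all()
    epd_ok = (
        (b["epd_band_lower"] >= r["epd_adaptive_lower"] - DURATION_ATOL)
        & (b["epd_band_upper"] <= r["epd_adaptive_upper"] + DURATION_ATOL)
    ).all()
    if not (rr_ok and epd_ok):
        raise ParameterError("band lies outside the theoretical limits")


def render_figures(
    result: SweepResult,
    band: Optional[LikelyBand] = None,
    outdir: Union[str, Path] = ".",
    formats: Iterable[str] = ("png",),
    normalized: bool = False,
    dpi: int = 150,
) -> list:
    """Render the RR and EPD panels for one sweep; returns written paths.

    ``normalized=True`` draws the duration panel as a percentage of each
    row's full-protocol duration (requires a sweep run with
    ``normalized=True``).
    """
    if len(result.table) == 0:
        raise ParameterError("cannot render an empty sweep result")
    if band is not None:
        _check_band(result, band)
    if normalized and "epd_full_only_pct_full" not in result.table.columns:
        raise ParameterError(
            "normalized rendering requires a sweep run with normalized=True"
        )

    x = result.table["value"].to_numpy()
    suffix = "_pct_full" if normalized else ""
    fig = Figure(figsize=(11, 4.2))
    ax_rr, ax_epd = fig.subplots(1, 2)

    # recall-rate panel (always on the fraction scale)
    t = result.table
    ax_rr.fill_between(
        x, t["rr_adaptive_lower"], t["rr_adaptive_upper"],
        color="#a8dba8", alpha=0.6, linewidth=0,
    )
    if band is not None:
        ax_rr.fill_between(
            x, band.table["rr_band_lower"], band.table["rr_band_upper"],
            color="#2e8b57", alpha=0.55, linewidth=0,
        )
        ax_rr.plot(x, band.table["rr_band_lower"], ":", color="#1d5c38", lw=1)
        ax_rr.plot(x, band.table["rr_band_upper"], ":", color="#1d5c38", lw=1)
    ax_rr.plot(x, t["rr_adaptive_lower"], color="green", lw=1.5)
    ax_rr.plot(x, t["rr_adaptive_upper"], color="green", lw=1.5)
    ax_rr.plot(x, t["rr_abbr_only"], color="red", lw=1.5, label="abbreviated only")
    ax_rr.plot(x, t["rr_full_only"], color="blue", lw=1.5, label="full only")
    ax_rr.set_xlabel(AXIS_LABELS.get(result.spec.parameter, result.spec.parameter))
    ax_rr.set_ylabel("recall rate")
    ax_rr.legend(loc="best", fontsize=8)

    # duration panel
    cols = {
        "lower": "epd_adaptive_lower" + suffix,
        "upper": "epd_adaptive_upper" + suffix,
        "abbr": "epd_abbr_only" + suffix,
        "full": "epd_full_only" + suffix,
    }
    ax_epd.fill_between(
        x, t[cols["lower"]], t[cols["upper"]],
        color="#a8dba8", alpha=0.6, linewidth=0,
    )
    if band is not None and not normalized:
        ax_epd.fill_between(
            x, band.table["epd_band_lower"], band.table["epd_band_upper"],
            color="#2e8b57", alpha=0.55, linewidth=0,
        )
        ax_epd.plot(x, band.table["epd_band_lower"], ":", color="#1d5c38", lw=1)
        ax_epd.plot(x, band.table["epd_band_upper"], ":", color="#1d5c38", lw=1)
    elif band is not None and normalized:
        scale = 100.0 / t["epd_full_only"].to_numpy()
        ax_epd.fill_between(
            x,
            band.table["epd_band_lower"] * scale,
            band.table["epd_band_upper"] * scale,
            color="#2e8b57", alpha=0.55, linewidth=0,
        )
    ax_epd.plot(x, t[cols["lower"]], color="green", lw=1.5)
    ax_epd.plot(x, t[cols["upper"]], color="green", lw=1.5)
    ax_epd.plot(x, t[cols["abbr"]], color="red", lw=1.5, label="abbreviated only")
    ax_epd.plot(x, t[cols["full"]], color="blue", lw=1.5, label="full only")
    ax_epd.set_xlabel(AXIS_LABELS.get(result.spec.parameter, result.spec.parameter))
    ax_epd.set_ylabel(
        "expected duration [% of full]" if normalized else "expected duration [s]"
    )
    ax_epd.legend(loc="best", fontsize=8)

    fig.tight_layout()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        path = outdir / f"sweep_{result.spec.parameter}.{fmt}"
        fig.savefig(path, dpi=dpi)
        written.append(path)
    return written
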