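"""Standard and prevalence-scaled ("modified") forest plots.

A standard forest plot places one trial per evenly spaced row, ordered by
input or chronologically; its vertical direction carries no quantitative
information.  The modified plot replaces the row axis with a true second
axis: each trial sits at the height of its subgroup prevalence, so the
vertical axis *scales* the subgrouping variable rather than merely ordering
it.  A treatment effect that drifts with prevalence then appears as a
diagonal trend — a pattern invisible to permutation-invariant heterogeneity
statistics, and invisible in the standard plot unless the reader happens to
know the prevalences.

Rendering is deterministic: the same layout always yields byte-identical
SVG (fixed element order, fixed float formatting, no timestamps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .effects import RATIO_MEASURES, confidence_interval, reporting_point
from .errors import MissingDataError
from .heterogeneity import MetaInput

# SVG canvas geometry (pixels); exposed so callers can map data coordinates
WIDTH, HEIGHT = 640, 480
PLOT_X0, PLOT_X1 = 150.0, 600.0
PLOT_Y0, PLOT_Y1 = 40.0, 420.0  # top, bottom

TIE_OFFSET = 0.015  # fraction of axis height per step between tied rows


@dataclass(frozen=True)
class ForestRow:
    label: str
    x_point: float      # reporting scale
    x_low: float
    x_high: float
    y_position: float   # fraction of the vertical axis, 0 = bottom
    subgroup_proportion: float | None
    weight: float       # inverse-variance weight, sets marker area


@dataclass(frozen=True)
class ForestLayout:
    rows: tuple[ForestRow, ...]
    measure: str
    y_mode: str         # "rank" or "proportion"
    level: float = 0.95

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if self.y_mode not in ("rank", "proportion"):
            raise ValueError(f"unknown y_mode {self.y_mode!r}")


def _rows_from_meta(meta: MetaInput) -> list[dict]:
    rows = []
    for i, est in enumerate(meta.estimates):
        low, high = confidence_interval(est, 0.95)
        rows.append(
            {
                "label": est.label,
                "point": reporting_point(est),
                "low": low,
                "high": high,
                "prop": meta.subgroup_props[i] if meta.subgroup_props else None,
                "year": meta.years[i] if meta.years else None,
                "weight": 1.0 / est.variance,
            }
        )
    return rows


def layout_standard(meta: MetaInput, order: str = "input") -> ForestLayout:
    """Evenly spaced rows, top to bottom, in input or chronological order."""
    rows = _rows_from_meta(meta)
    if order == "chronological":
        if any(r["year"] is None for r in rows):
            raise MissingDataError("chronological order requested but years are missing")
        rows.sort(key=lambda r: (r["year"], r["label"]))
    elif order != "input":
        raise ValueError(f"unknown order {order!r}")
    k = len(rows)
    out = []
    for j, r in enumerate(rows):
        y = 0.5 if k == 1 else 1.0 - j / (k - 1)
        out.append(
            ForestRow(
                label=r["label"],
                x_point=r["point"],
                x_low=r["low"],
                x_high=r["high"],
                y_position=y,
                subgroup_proportion=r["prop"],
                weight=r["weight"],
            )
        )
    return ForestLayout(rows=tuple(out), measure=meta.measure, y_mode="rank")


def layout_modified(meta: MetaInput) -> ForestLayout:
    """Rows placed at their subgroup prevalence on a 0-100% vertical axis.

    Trials with equal prevalence receive deterministic offsets of up to
    +-1.5% of the axis height, assigned in label-lexicographic order, so
    coincident rows stay distinguishable.  Row order in the output follows
    prevalence (then label), making the layout invariant to input order.
    """
    rows = _rows_from_meta(meta)
    if any(r["prop"] is None for r in rows):
        raise MissingDataError("modified layout needs a subgroup proportion per trial")
    rows.sort(key=lambda r: (r["prop"], r["label"]))
    # group ties and spread them symmetrically
    y_positions: list[float] = []
    i = 0
    while i < len(rows):
        j = i
        while j < len(rows) and rows[j]["prop"] == rows[i]["prop"]:
            j += 1
        m = j - i
        for t in range(m):
            off = 0.0 if m == 1 else -TIE_OFFSET + 2 * TIE_OFFSET * t / (m - 1)
            y_positions.append(rows[i]["prop"] + off)
        i = j
    out = [
        ForestRow(
            label=r["label"],
            x_point=r["point"],
            x_low=r["low"],
            x_high=r["high"],
            y_position=y,
            subgroup_proportion=r["prop"],
            weight=r["weight"],
        )
        for r, y in zip(rows, y_positions)
    ]
    return ForestLayout(rows=tuple(out), measure=meta.measure, y_mode="proportion")


# ------------------------------------------------------------------ scales

def _null_value(measure: str) -> float:
    return 1.0 if measure in RATIO_MEASURES else 0.0


def _x_range(layout: ForestLayout) -> tuple[float, float]:
    """Axis range on the transformed (log or linear) scale, symmetric about
    the no-effect value, covering all finite CI endpoints with 10% padding."""
    log = layout.measure in RATIO_MEASURES
    ext = 0.0
    for r in layout.rows:
        for v in (r.x_low, r.x_point, r.x_high):
            if not math.isfinite(v) or (log and v <= 0):
                continue
            u = math.log(v) if log else v
            ext = max(ext, abs(u))
    if ext == 0.0:
        ext = math.log(2.0) if log else 0.5
    ext *= 1.10
    return -ext, ext


def _to_axis(v: float, layout: ForestLayout) -> float | None:
    log = layout.measure in RATIO_MEASURES
    if not math.isfinite(v) or (log and v <= 0):
        return None
    return math.log(v) if log else v


# --------------------------------------------------------------- rendering

def render(layout: ForestLayout, format: str = "svg") -> str:
    """Render a layout as an SVG 1.1 document or a monospace text sketch."""
    if format == "svg":
        return _render_svg(layout)
    if format == "text":
        return _render_text(layout)
    raise ValueError(f"unknown format {format!r}")


def _f(v: float) -> str:
    return f"{v:.2f}"


def _xpix(u: float, umin: float, umax: float) -> float:
    return PLOT_X0 + (u - umin) / (umax - umin) * (PLOT_X1 - PLOT_X0)


def _ypix(y: float) -> float:
    return PLOT_Y1 - y * (PLOT_Y1 - PLOT_Y0)


def _axis_tick_values(layout: ForestLayout, umin: float, umax: float) -> list[float]:
    if layout.measure in RATIO_MEASURES:
        candidates = [0.1, 0.2, 0.25, 0.5, 0.7, 1.0, 1.5, 2.0, 4.0, 5.0, 10.0]
        return [v for v in candidates if umin <= math.log(v) <= umax]
    span = umax - umin
    step = 10 ** math.floor(math.log10(span / 4)) if span > 0 else 0.1
    if span / step > 8:
        step *= 2
    first = math.ceil(umin / step)
    return [round(i * step, 10) for i in range(first, math.floor(umax / step) + 1)]


def _render_svg(layout: ForestLayout) -> str:
    umin, umax = _x_range(layout)
    null = _null_value(layout.measure)
    e: list[str] = []
    e.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{WIDTH}" height="{HEIGHT}" viewBox="0 0 {WIDTH} {HEIGHT}">'
    )
    e.append(f'<rect x="0" y="0" width="{WIDTH}" height="{HEIGHT}" fill="white"/>')
    # frame
    e.append(
        f'<line x1="{_f(PLOT_X0)}" y1="{_f(PLOT_Y1)}" x2="{_f(PLOT_X1)}" '
        f'y2="{_f(PLOT_Y1)}" stroke="black" stroke-width="1"/>'
    )
    # x ticks + labels
    for v in _axis_tick_values(layout, umin, umax):
        u = math.log(v) if layout.measure in RATIO_MEASURES else v
        xp = _xpix(u, umin, umax)
        e.append(
            f'<line x1="{_f(xp)}" y1="{_f(PLOT_Y1)}" x2="{_f(xp)}" '
            f'y2="{_f(PLOT_Y1 + 5)}" stroke="black" stroke-width="1"/>'
        )
        e.append(
            f'<text x="{_f(xp)}" y="{_f(PLOT_Y1 + 18)}" font-size="11" '
            f'text-anchor="middle" font-family="monospace">{v:g}</text>'
        )
    xlabel = {"log-rr": "risk ratio", "log-or": "odds ratio", "rd": "risk difference"}[
        layout.measure
    ]
    e.append(
        f'<text x="{_f((PLOT_X0 + PLOT_X1) / 2)}" y="{_f(PLOT_Y1 + 36)}" '
        f'font-size="12" text-anchor="middle" font-family="monospace">{xlabel}'
        f"{' (log scale)' if layout.measure in RATIO_MEASURES else ''}</text>"
    )
    # dashed no-effect reference line
    null_x = _xpix(math.log(null) if layout.measure in RATIO_MEASURES else null, umin, umax)
    e.append(
        f'<line x1="{_f(null_x)}" y1="{_f(PLOT_Y0)}" x2="{_f(null_x)}" '
        f'y2="{_f(PLOT_Y1)}" stroke="black" stroke-width="1" '
        f'stroke-dasharray="6,4" class="no-effect"/>'
    )
    # vertical subgroup-proportion axis for the modified plot
    if layout.y_mode == "proportion":
        e.append(
            f'<line x1="{_f(PLOT_X0)}" y1="{_f(PLOT_Y0)}" x2="{_f(PLOT_X0)}" '
            f'y2="{_f(PLOT_Y1)}" stroke="black" stroke-width="1"/>'
        )
        for pct in (0, 25, 50, 75, 100):
            yp = _ypix(pct / 100.0)
            e.append(
                f'<line x1="{_f(PLOT_X0 - 5)}" y1="{_f(yp)}" x2="{_f(PLOT_X0)}" '
                f'y2="{_f(yp)}" stroke="black" stroke-width="1"/>'
            )
            e.append(
                f'<text x="{_f(PLOT_X0 - 9)}" y="{_f(yp + 4)}" font-size="11" '
                f'text-anchor="end" font-family="monospace">{pct}%</text>'
            )
        e.append(
            f'<text x="18" y="{_f((PLOT_Y0 + PLOT_Y1) / 2)}" font-size="12" '
            f'text-anchor="middle" font-family="monospace" '
            f'transform="rotate(-90 18 {_f((PLOT_Y0 + PLOT_Y1) / 2)})">'
            f"subgroup proportion</text>"
        )
    # rows: whisker, clip arrows, marker, label
    wmin = min((r.weight for r in layout.rows), default=1.0)
    for r in layout.rows:
        yp = _ypix(r.y_position)
        ulow, uhigh = _to_axis(r.x_low, layout), _to_axis(r.x_high, layout)
        clip_lo = ulow is None or ulow < umin
        clip_hi = uhigh is None or uhigh > umax
        xl = umin if clip_lo else max(ulow, umin)
        xh = umax if clip_hi else min(uhigh, umax)
        xlp, xhp = _xpix(xl, umin, umax), _xpix(xh, umin, umax)
        e.append(
            f'<line x1="{_f(xlp)}" y1="{_f(yp)}" x2="{_f(xhp)}" y2="{_f(yp)}" '
            f'stroke="black" stroke-width="1" class="whisker"/>'
        )
        if clip_lo:
            e.append(
                f'<path d="M {_f(xlp + 8)} {_f(yp - 4)} L {_f(xlp)} {_f(yp)} '
                f'L {_f(xlp + 8)} {_f(yp + 4)}" stroke="black" fill="none" class="clip-arrow"/>'
            )
        if clip_hi:
            e.append(
                f'<path d="M {_f(xhp - 8)} {_f(yp - 4)} L {_f(xhp)} {_f(yp)} '
                f'L {_f(xhp - 8)} {_f(yp + 4)}" stroke="black" fill="none" class="clip-arrow"/>'
            )
        up = _to_axis(r.x_point, layout)
        if up is not None and umin <= up <= umax:
            radius = 3.0 * math.sqrt(min(r.weight, 5.0 * wmin) / wmin)
            e.append(
                f'<circle cx="{_f(_xpix(up, umin, umax))}" cy="{_f(yp)}" '
                f'r="{_f(radius)}" fill="black" class="marker"/>'
            )
        label_x = PLOT_X0 - (60.0 if layout.y_mode == "proportion" else 10.0)
        e.append(
            f'<text x="{_f(label_x)}" y="{_f(yp + 4)}" font-size="11" '
            f'text-anchor="end" font-family="monospace" class="row-label">{r.label}</text>'
        )
    e.append("</svg>")
    return "\n".join(e) + "\n"


def _render_text(layout: ForestLayout, width: int = 60, label_width: int = 12) -> str:
    """Fixed-width sketch: one line per row, an axis line, an endpoints line."""
    umin, umax = _x_range(layout)
    null_u = math.log(_null_value(layout.measure)) if layout.measure in RATIO_MEASURES else 0.0
    null_col = round((null_u - umin) / (umax - umin) * (width - 1))

    def col(v: float) -> int | None:
        u = _to_axis(v, layout)
        if u is None:
            return None
        return round((u - umin) / (umax - umin) * (width - 1))

    rows = sorted(layout.rows, key=lambda r: -r.y_position)
    lines = []
    for r in rows:
        line = [" "] * width
        line[null_col] = "|"
        lo, hi = col(r.x_low), col(r.x_high)
        lo = 0 if lo is None else max(lo, 0)
        hi = width - 1 if hi is None else min(hi, width - 1)
        for cidx in range(lo, hi + 1):
            line[cidx] = "-"
        line[lo] = "<" if col(r.x_low) is None or col(r.x_low) < 0 else "+"
        line[hi] = ">" if col(r.x_high) is None or col(r.x_high) > width - 1 else "+"
        pc = col(r.x_point)
        if pc is not None and 0 <= pc < width:
            line[pc] = "x"
        tag = (
            f"{r.subgroup_proportion * 100:5.1f}% "
            if layout.y_mode == "proportion" and r.subgroup_proportion is not None
            else ""
        )
        lines.append(f"{(tag + r.label)[:label_width]:<{label_width}}{''.join(line)}")
    axis = [" "] * width
    axis[null_col] = "|"
    lines.append(f"{'':<{label_width}}{''.join(axis)}")
    log = layout.measure in RATIO_MEASURES
    left = math.exp(umin) if log else umin
    right = math.exp(umax) if log else umax
    nullv = _null_value(layout.measure)
    scale_line = [" "] * width
    for v, anchor in ((left, 0), (nullv, null_col), (right, width - 1)):
        s = f"{v:g}"
        start = min(max(anchor - len(s) // 2, 0), width - len(s))
        for i, ch in enumerate(s):
            scale_line[start + i] = ch
    lines.append(f"{'':<{label_width}}{''.join(scale_line)}")
    return "\n".join(lines) + "\n"
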