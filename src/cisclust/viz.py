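"""Schematic rendering of candidate enhancer modules along an upstream region.

The drawing encodes, per region: which factors bind in each module (one
fixed colour per factor), how many sites a module holds, their linear
order, sites overlapping a different factor's site, and each module's
relative position and length within the upstream region.  Deliberately
*not* encoded: strand, to-scale spacing inside a module, per-site length,
and nucleotide composition — glyphs are equal-width boxes packed in site
order, which keeps module site density legible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .catalog import TFClass, TF_COLORS
from .clusters import EnhancerModule

__all__ = ["color_of", "Glyph", "RegionTrack", "layout_region", "render_svg", "render_text"]


class VizError(ValueError):
    pass


def color_of(tf: TFClass) -> str:
    """The fixed display colour of a transcription-factor class."""
    if not isinstance(tf, TFClass):
        raise VizError(f"unknown TF class {tf!r}")
    return TF_COLORS[tf]


@dataclass(frozen=True)
class Glyph:
    """One drawable binding site inside a module box."""

    tf_class: TFClass
    color: str
    order: int  # 0-based position in start order within the module
    overlaps_other_tf: bool


@dataclass(frozen=True)
class ModuleBox:
    module: EnhancerModule
    frac_start: float  # [0, 1) offset of the box along the track
    frac_width: float
    glyphs: tuple[Glyph, ...]


@dataclass(frozen=True)
class RegionTrack:
    region_id: str
    region_length: int
    boxes: tuple[ModuleBox, ...]

    @property
    def n_glyphs(self) -> int:
        return sum(len(b.glyphs) for b in self.boxes)


def layout_region(
    modules: Sequence[EnhancerModule], region_length: int
) -> RegionTrack:
    """Position module boxes proportionally along the region.

    Box x-offset and width are start/length over region length; glyphs are
    laid out in hit start order; a glyph's overlap flag is set iff its hit
    span intersects a hit of a *different* TF class in the same module.
    """
    if region_length < 1:
        raise VizError("region_length must be >= 1")
    region_ids = {m.region_id for m in modules}
    if len(region_ids) > 1:
        raise VizError(f"modules from multiple regions: {sorted(region_ids)}")
    boxes = []
    for mod in sorted(modules, key=lambda m: m.start):
        if mod.start < 1 or mod.end > region_length:
            raise VizError(
                f"module [{mod.start},{mod.end}] outside region of length {region_length}"
            )
        hits = sorted(mod.member_hits, key=lambda h: (h.start, h.end, h.tf_class.value))
        glyphs = tuple(
            Glyph(
                tf_class=h.tf_class,
                color=color_of(h.tf_class),
                order=i,
                overlaps_other_tf=any(
                    h.overlaps(o) and o.tf_class is not h.tf_class for o in hits
                ),
            )
            for i, h in enumerate(hits)
        )
        boxes.append(
            ModuleBox(
                module=mod,
                frac_start=(mod.start - 1) / region_length,
                frac_width=(mod.end - mod.start + 1) / region_length,
                glyphs=glyphs,
            )
        )
    return RegionTrack(
        region_id=modules[0].region_id if modules else "",
        region_length=region_length,
        boxes=tuple(boxes),
    )


# -- rendering ---------------------------------------------------------------

_TRACK_W = 900.0
_TRACK_H = 110.0
_BOX_Y = 40.0
_BOX_H = 40.0


def render_svg(track: RegionTrack) -> str:
    """Deterministic SVG 1.1 document; one <rect> glyph per binding site.

    Glyphs with the overlap flag are outlined black so co-bound sites of
    different factors stand out.
    """
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_TRACK_W:.0f}" height="{_TRACK_H:.0f}">',
        f'<text x="4" y="16" font-family="monospace" font-size="14">'
        f"{track.region_id}</text>",
        f'<line x1="0" y1="{_BOX_Y + _BOX_H / 2:.1f}" x2="{_TRACK_W:.0f}" '
        f'y2="{_BOX_Y + _BOX_H / 2:.1f}" stroke="gray" stroke-width="1"/>',
    ]
    for box in track.boxes:
        bx = box.frac_start * _TRACK_W
        bw = box.frac_width * _TRACK_W
        parts.append(
            f'<rect x="{bx:.2f}" y="{_BOX_Y:.1f}" width="{bw:.2f}" '
            f'height="{_BOX_H:.1f}" fill="none" stroke="black" stroke-width="1"/>'
        )
        n = len(box.glyphs)
        pad = 2.0
        gw = (bw - pad * (n + 1)) / n if n else 0.0
        for g in box.glyphs:
            gx = bx + pad + g.order * (gw + pad)
            stroke = "black" if g.overlaps_other_tf else "none"
            parts.append(
                f'<rect class="glyph" x="{gx:.2f}" y="{_BOX_Y + 4:.1f}" '
                f'width="{gw:.2f}" height="{_BOX_H - 8:.1f}" fill="{g.color}" '
                f'stroke="{stroke}" stroke-width="2"/>'
            )
        mod = box.module
        parts.append(
            f'<text x="{bx:.2f}" y="{_BOX_Y + _BOX_H + 16:.1f}" '
            f'font-family="monospace" font-size="11">{mod.start}-{mod.end}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_text(track: RegionTrack, width: int = 75) -> str:
    """Plain-text mirror of the layout: one character column per region slice.

    Module extents are bracketed; inside each module the member sites are
    listed in order with one-letter factor codes (C=CREB, F=FOXD3, L=LEF1,
    M=MITF, P=POU3F2, U=USF1; '*' marks a site overlapping another factor).
    """
    letter = {tf: tf.value[0] for tf in TFClass}
    ruler = ["-"] * width
    for box in track.boxes:
        a = int(box.frac_start * width)
        b = max(a, min(width - 1, int((box.frac_start + box.frac_width) * width) - 1))
        ruler[a] = "["
        ruler[b] = "]"
        for i in range(a + 1, b):
            ruler[i] = "="
    lines = [f"{track.region_id} ({track.region_length} nt)", "".join(ruler)]
    for box in track.boxes:
        mod = box.module
        sites = "".join(
            letter[g.tf_class] + ("*" if g.overlaps_other_tf else "")
            for g in box.glyphs
        )
        lines.append(
            f"  [{mod.start:>4}-{mod.end:>4}] rank {mod.rank} "
            f"n={mod.n_sites} sites={sites}"
        )
    return "\n".join(lines) + "\n"


def write_svg(track: RegionTrack, path: str | Path) -> None:
    Path(path).write_text(render_svg(track))
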