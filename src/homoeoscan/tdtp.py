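"""Transcriptome Display Tile Plots (TDTPs) in CMYK colour space.

Each column is a homoeologue group in genome order, each row a sample, and
the tile colour encodes relative subgenome abundance: every member gene is
scaled across the plotted population to [0, 1] (1 = the sample with the
highest abundance, darkest), and each genome's scaled value drives one CMYK
channel. A balanced A/C pair saturates cyan and magenta together and
renders blue; an exchange leaves only one channel and renders pure cyan or
magenta; a balanced triplet saturates cyan/magenta/yellow and renders
neutral grey. Because scaling is per gene, colours depend only on relative
abundance within each homoeologue set — the property that makes the plots
robust across replicates and between mRNA-seq and DNA-coverage inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .types import ExpressionPanel, ValidationError

__all__ = [
    "normalize_abundance",
    "encode_cmyk",
    "cmyk_to_rgb",
    "render_tdtp",
    "TilePlotSpec",
    "DEFAULT_CHANNELS",
]

CHANNELS = ("cyan", "magenta", "yellow")

#: Conventional channel assignment: first genome (alphabetically) to cyan,
#: second to magenta, third to yellow.
DEFAULT_CHANNELS = {0: "cyan", 1: "magenta", 2: "yellow"}


def default_channel_map(genomes) -> dict[str, str]:
    genomes = sorted(genomes)
    if len(genomes) > 3:
        raise ValidationError("at most three genomes can be colour-coded")
    return {g: CHANNELS[i] for i, g in enumerate(genomes)}


def normalize_abundance(
    panel: ExpressionPanel,
    groups,
    percentile_cap: float | None = None,
) -> pd.DataFrame:
    """Scale each member gene across the population of samples to [0, 1].

    ``v' = v / max_over_samples(v)`` (all-zero genes stay 0). With
    ``percentile_cap=q`` the divisor is the q-th percentile instead, and
    values are clipped to 1 — an outlier-resistant variant. Monotone:
    larger RPKM never yields a smaller scaled value.
    """
    genes = sorted({gene for g in groups for gene in g.members.values()})
    missing = [g for g in genes if g not in panel.values.index]
    if missing:
        raise ValidationError(f"panel lacks member genes, e.g. {missing[:5]}")
    sub = panel.values.loc[genes]
    arr = sub.to_numpy(dtype=float)
    if percentile_cap is None:
        denom = arr.max(axis=1)
    else:
        denom = np.percentile(arr, percentile_cap, axis=1)
    denom = np.where(denom <= 0, 1.0, denom)
    out = np.clip(arr / denom[:, None], 0.0, 1.0)
    # values tied with the population maximum up to float rounding are the
    # maximum; snap so full saturation is exact
    out[out > 1.0 - 1e-12] = 1.0
    return pd.DataFrame(out, index=sub.index, columns=sub.columns)


@dataclass
class TilePlotSpec:
    """Channel values ready for rendering.

    ``channels`` maps channel name -> (n_rows x n_cols) array in [0, 1];
    rows follow ``row_labels`` (samples), columns follow ``groups`` in
    genome order. ``chromosomes`` gives the chromosome of each column, so
    renderers can draw boundaries. ``annotations`` is a list of
    (column_index, label) gene markers.
    """

    channels: dict
    row_labels: list
    groups: list
    chromosomes: list
    channel_map: dict
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any() or (arr > 1).any():
                raise ValidationError(f"channel {name!r} outside [0, 1]")
            self.channels[name] = arr
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError("channel arrays differ in shape")
        (self.shape,) = shapes
        if self.shape != (len(self.row_labels), len(self.groups)):
            raise ValidationError("channel shape does not match rows x groups")

    def cmyk(self, row: int, col: int) -> tuple[float, float, float, float]:
        c = self.channels.get("cyan", np.zeros(self.shape))[row, col]
        m = self.channels.get("magenta", np.zeros(self.shape))[row, col]
        y = self.channels.get("yellow", np.zeros(self.shape))[row, col]
        return float(c), float(m), float(y), 0.0

    def to_frame(self) -> pd.DataFrame:
        """Sidecar table of per-tile CMYK values for programmatic checks."""
        rows = []
        for i, sample in enumerate(self.row_labels):
            for j, grp in enumerate(self.groups):
                c, m, y, k = self.cmyk(i, j)
                rows.append(
                    {
                        "sample_id": sample,
                        "group_id": grp.group_id,
                        "chromosome": self.chromosomes[j],
                        "ordinal": grp.ordinal,
                        "c": c,
                        "m": m,
                        "y": y,
                        "k": k,
                    }
                )
        return pd.DataFrame(rows)


def encode_cmyk(
    normalized: pd.DataFrame,
    groups,
    channel_map: dict[str, str] | None = None,
    row_order=None,
    collapse_accessions: bool = False,
    sample_sheet=None,
    annotations=None,
) -> TilePlotSpec:
    """Bind each genome's normalized abundance to a CMYK channel.

    ``channel_map`` maps genome -> channel (injective over cyan / magenta /
    yellow); default assigns genomes alphabetically. ``collapse_accessions``
    averages replicate rows per accession (the large-panel layout);
    otherwise replicates appear as adjacent rows.
    """
    genomes = sorted({g for grp in groups for g in grp.members})
    if channel_map is None:
        channel_map = default_channel_map(genomes)
    used = list(channel_map.values())
    if len(set(used)) != len(used):
        raise ValidationError("two genomes mapped to one channel")
    bad = set(used) - set(CHANNELS)
    if bad:
        raise ValidationError(f"unknown channels: {sorted(bad)}")
    if set(channel_map) != set(genomes):
        raise ValidationError(
            f"channel map genomes {sorted(channel_map)} != group genomes {genomes}"
        )

    groups = sorted(groups, key=lambda g: (g.chromosome, g.ordinal))
    if row_order is None:
        row_order = list(normalized.columns)
    if collapse_accessions:
        if sample_sheet is None:
            raise ValidationError("collapse_accessions requires a sample sheet")
        acc_order = list(dict.fromkeys(
            sample_sheet.frame.set_index("sample_id").loc[row_order, "accession_id"]
        ))
        collapsed = {}
        for acc in acc_order:
            cols = [s for s in sample_sheet.samples_of(acc) if s in row_order]
            collapsed[acc] = normalized[cols].mean(axis=1)
        normalized = pd.DataFrame(collapsed)
        row_order = acc_order

    n_rows, n_cols = len(row_order), len(groups)
    channels = {ch: np.zeros((n_rows, n_cols)) for ch in CHANNELS}
    for genome, channel in channel_map.items():
        genes = [g.members[genome] for g in groups]
        channels[channel] = (
            normalized.loc[genes, row_order].to_numpy(dtype=float).T
        )
    ann = []
    if annotations:
        by_gene = {
            gene: j for j, g in enumerate(groups) for gene in g.members.values()
        }
        for gene_id, label in annotations:
            if gene_id in by_gene:
                ann.append((by_gene[gene_id], label))
    return TilePlotSpec(
        channels=channels,
        row_labels=list(row_order),
        groups=groups,
        chromosomes=[g.chromosome for g in groups],
        channel_map=dict(channel_map),
        annotations=ann,
    )


def cmyk_to_rgb(c, m, y, k=0.0):
    """Standard naive CMYK -> RGB: r=(1-c)(1-k), g=(1-m)(1-k), b=(1-y)(1-k)."""
    arrs = [np.asarray(v, dtype=float) for v in (c, m, y, k)]
    for name, a in zip("cmyk", arrs):
        if (a < 0).any() or (a > 1).any():
            raise ValidationError(f"channel {name!r} outside [0, 1]")
    c, m, y, k = arrs
    r = (1.0 - c) * (1.0 - k)
    g = (1.0 - m) * (1.0 - k)
    b = (1.0 - y) * (1.0 - k)
    if r.ndim == 0:
        return float(r), float(g), float(b)
    return r, g, b


GAP_COLOUR = (255, 255, 255)
MARKER_COLOUR = (0, 0, 0)


def _rgb_matrix(spec: TilePlotSpec) -> np.ndarray:
    r, g, b = cmyk_to_rgb(
        spec.channels.get("cyan", np.zeros(spec.shape)),
        spec.channels.get("magenta", np.zeros(spec.shape)),
        spec.channels.get("yellow", np.zeros(spec.shape)),
    )
    rgb = np.stack([r, g, b], axis=-1)
    return np.rint(rgb * 255.0).astype(np.uint8)


def _column_layout(spec: TilePlotSpec, tile_w: int, gap: int):
    """x offset (in px) of each tile column, with gaps at chromosome
    boundaries and 1-px marker lines before annotated columns."""
    marker_cols = {j for j, _ in spec.annotations}
    xs, x = [], 0
    prev_chrom = None
    for j, chrom in enumerate(spec.chromosomes):
        if prev_chrom is not None and chrom != prev_chrom:
            x += gap
        if j in marker_cols:
            x += 1  # marker line occupies one pixel column
        xs.append(x)
        x += tile_w
        prev_chrom = chrom
    return xs, x


def render_tdtp(
    spec: TilePlotSpec,
    out_path,
    tile_size: tuple[int, int] = (1, 1),
    chromosome_gap: int = 2,
    fmt: str | None = None,
) -> None:
    """Render a tile-plot spec to PNG or SVG (chosen by extension or
    ``fmt``). One tile per (group, sample); chromosome boundaries appear as
    white gap columns, annotated genes as 1-px black marker lines. Output
    is deterministic for fixed input and options."""
    if spec.shape[0] == 0 or spec.shape[1] == 0:
        raise ValidationError("empty tile plot spec")
    out_path = str(out_path)
    if fmt is None:
        fmt = "svg" if out_path.lower().endswith(".svg") else "png"
    tile_w, tile_h = tile_size
    if tile_w < 1 or tile_h < 1:
        raise ValidationError("tile size must be >= 1 px")
    rgb = _rgb_matrix(spec)
    xs, width = _column_layout(spec, tile_w, chromosome_gap)
    height = spec.shape[0] * tile_h
    if fmt == "png":
        img = np.empty((height, width, 3), dtype=np.uint8)
        img[:] = GAP_COLOUR
        for j, x in enumerate(xs):
            tiles = np.repeat(
                np.repeat(rgb[:, j][:, None, :], tile_h, axis=0), tile_w, axis=1
            ).reshape(height, tile_w, 3)
            img[:, x : x + tile_w] = tiles
        for j, _label in spec.annotations:
            img[:, xs[j] - 1] = MARKER_COLOUR
        Image.fromarray(img, mode="RGB").save(out_path, format="PNG")
    elif fmt == "svg":
        lines = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
            f'height="{height}" shape-rendering="crispEdges">',
            f'<rect width="{width}" height="{height}" fill="#ffffff"/>',
        ]
        for j, x in enumerate(xs):
            for i in range(spec.shape[0]):
                r, g, b = rgb[i, j]
                lines.append(
                    f'<rect x="{x}" y="{i * tile_h}" width="{tile_w}" '
                    f'height="{tile_h}" fill="#{r:02x}{g:02x}{b:02x}"/>'
                )
        for j, label in spec.annotations:
            lines.append(
                f'<rect x="{xs[j] - 1}" y="0" width="1" height="{height}" '
                f'fill="#000000"><title>{label}</title></rect>'
            )
        lines.append("</svg>")
        with open(out_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown output format {fmt!r}")


def tile_pixel(
    spec: TilePlotSpec,
    row: int,
    col: int,
    tile_size: tuple[int, int] = (1, 1),
    chromosome_gap: int = 2,
) -> tuple[int, int]:
    """(x, y) pixel at the centre of a tile, for rendering-fidelity checks."""
    xs, _ = _column_layout(spec, tile_size[0], chromosome_gap)
    x = xs[col] + tile_size[0] // 2
    y = row * tile_size[1] + tile_size[1] // 2
    return x, y
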