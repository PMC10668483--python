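"""Gaussian attribution heat-maps composited under 2D reaction depictions.

Atom weights (from the attribution module) are normalised across the whole
reaction, placed at the 2D drawing coordinates of their atoms, and expanded
into a pixel field

    G(x, y) = sum_j w_j * exp(-((x - x_j)^2 + (y - y_j)^2) / (2 sigma^2)),

an isotropic Gaussian per atom.  The field is rendered on a diverging
colour scale — positive contributions green, negative magenta, zero
transparent — rasterised at a modest resolution and upscaled without
interpolation, with the molecule drawing composited on top.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from rdkit import Chem
from rdkit.Chem import rdDepictor

from .chem_io import ReactionRecord, parse_reaction_smiles
from .errors import InputError

__all__ = [
    "DepictionLayout",
    "MoleculeLayout",
    "HeatmapGrid",
    "RenderParams",
    "layout_reaction",
    "normalize_atom_weights",
    "heatmap_grid",
    "heatmap_for_layout",
    "render_explanation",
    "render_reaction",
    "absent_fragment_report",
]


@dataclass
class MoleculeLayout:
    symbols: list[str]
    charges: list[int]
    coords: np.ndarray  # (n_atoms, 2) drawing units, offset applied
    bonds: list[tuple[int, int, float]]  # begin, end, bond order
    bbox: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


@dataclass
class DepictionLayout:
    molecules: list[MoleculeLayout]
    n_reactants: int  # molecules[:n_reactants] are the reactant side
    arrow: tuple[float, float, float]  # x_start, x_end, y
    median_bond_length: float
    extent: tuple[float, float, float, float]


@dataclass
class HeatmapGrid:
    values: np.ndarray  # (H, W); row i is y = ymin + i / ppu
    extent: tuple[float, float, float, float]
    sigma: float
    ppu: int
    weights: np.ndarray


@dataclass(frozen=True)
class RenderParams:
    sigma: Optional[float] = None  # default: 0.3 x median bond length
    ppu: int = 20  # heat-raster pixels per drawing unit
    upscale: int = 2  # nearest-neighbour upscale factor for the final image
    padding: float = 1.0  # drawing units around the reaction
    alpha_max: int = 190
    positive_color: tuple[int, int, int] = (40, 170, 60)  # green
    negative_color: tuple[int, int, int] = (205, 50, 205)  # magenta

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise InputError("sigma must be positive")
        if self.ppu < 1 or self.upscale < 1:
            raise InputError("ppu and upscale must be positive")


_MOL_GAP = 1.6  # drawing units between molecules on one side
_ARROW_LEN = 2.5


def _molecule_layout(mol: Chem.Mol) -> MoleculeLayout:
    rdDepictor.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
                       for i in range(mol.GetNumAtoms())])
    # centre vertically, shift left edge to 0
    coords[:, 0] -= coords[:, 0].min()
    coords[:, 1] -= (coords[:, 1].min() + coords[:, 1].max()) / 2.0
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    bbox = (
        float(coords[:, 0].min()),
        float(coords[:, 1].min()),
        float(coords[:, 0].max()),
        float(coords[:, 1].max()),
    )
    return MoleculeLayout(
        symbols=[a.GetSymbol() for a in mol.GetAtoms()],
        charges=[a.GetFormalCharge() for a in mol.GetAtoms()],
        coords=coords,
        bonds=bonds,
        bbox=bbox,
    )


def layout_reaction(record: ReactionRecord | str) -> DepictionLayout:
    """Deterministic 2D layout: reactants, arrow, products left-to-right.

    Agents are merged into the reactant side so molecule indices line up
    with fingerprint occurrences.
    """
    smiles = record if isinstance(record, str) else record.reaction_smiles
    reactants, agents, products = parse_reaction_smiles(smiles)
    reactant_mols = reactants + agents
    layouts = [_molecule_layout(m) for m in reactant_mols + products]
    n_reactants = len(reactant_mols)

    cursor = 0.0
    for i, ml in enumerate(layouts):
        if i == n_reactants:
            arrow = (cursor + 0.4, cursor + 0.4 + _ARROW_LEN, 0.0)
            cursor += _ARROW_LEN + 0.8
        ml.coords[:, 0] += cursor
        ml.bbox = (
            ml.bbox[0] + cursor,
            ml.bbox[1],
            ml.bbox[2] + cursor,
            ml.bbox[3],
        )
        cursor = ml.bbox[2] + _MOL_GAP

    lengths = []
    for ml in layouts:
        for a, b, _ in ml.bonds:
            lengths.append(float(np.linalg.norm(ml.coords[a] - ml.coords[b])))
    median_bond = float(np.median(lengths)) if lengths else 1.5

    xmin = min(ml.bbox[0] for ml in layouts)
    xmax = max(ml.bbox[2] for ml in layouts)
    ymin = min(ml.bbox[1] for ml in layouts)
    ymax = max(ml.bbox[3] for ml in layouts)
    return DepictionLayout(
        molecules=layouts,
        n_reactants=n_reactants,
        arrow=arrow,
        median_bond_length=median_bond,
        extent=(xmin, ymin, xmax, ymax),
    )


def normalize_atom_weights(atom_weights):
    """Divide every weight by the max |w| over the whole reaction -> [-1, 1].

    Accepts a dict keyed by (molecule, atom) or an array; all-zero input is
    returned unchanged.  Signs are preserved.
    """
    if isinstance(atom_weights, dict):
        if not atom_weights:
            return dict(atom_weights)
        peak = max(abs(w) for w in atom_weights.values())
        if peak == 0:
            return dict(atom_weights)
        return {k: w / peak for k, w in atom_weights.items()}
    arr = np.asarray(atom_weights, dtype=np.float64)
    if arr.size == 0:
        raise InputError("need at least one atom weight")
    peak = np.abs(arr).max()
    return arr if peak == 0 else arr / peak


def heatmap_grid(
    coords: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    ppu: int = 20,
    extent: Optional[tuple[float, float, float, float]] = None,
    padding: float = 1.0,
) -> HeatmapGrid:
    """Evaluate the summed-Gaussian field on a pixel grid.

    Grid samples sit at x = xmin + i/ppu, y = ymin + j/ppu (corner
    convention), so integer drawing coordinates fall exactly on samples.
    """
    if sigma <= 0:
        raise InputError("sigma must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    weights = np.asarray(weights, dtype=np.float64).ravel()
    if coords.shape[0] != weights.shape[0]:
        raise InputError("coords and weights must have matching lengths")
    if extent is None:
        extent = (
            coords[:, 0].min() - padding,
            coords[:, 1].min() - padding,
            coords[:, 0].max() + padding,
            coords[:, 1].max() + padding,
        )
    xmin, ymin, xmax, ymax = extent
    xs = xmin + np.arange(int(round((xmax - xmin) * ppu)) + 1) / ppu
    ys = ymin + np.arange(int(round((ymax - ymin) * ppu)) + 1) / ppu
    gx, gy = np.meshgrid(xs, ys)
    values = np.zeros_like(gx)
    inv = 1.0 / (2.0 * sigma * sigma)
    for (x0, y0), w in zip(coords, weights):
        if w == 0.0:
            continue
        values += w * np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) * inv)
    return HeatmapGrid(values=values, extent=extent, sigma=sigma, ppu=ppu, weights=weights)


def heatmap_for_layout(
    layout: DepictionLayout,
    atom_weights: dict[tuple[int, int], float],
    params: RenderParams,
) -> HeatmapGrid:
    """Heat-map over the whole reaction canvas from (molecule, atom) weights."""
    coords, weights = [], []
    for (mi, ai), w in sorted(atom_weights.items()):
        if mi >= len(layout.molecules) or ai >= len(layout.molecules[mi].symbols):
            raise InputError(f"atom weight references unknown atom ({mi}, {ai})")
        coords.append(layout.molecules[mi].coords[ai])
        weights.append(w)
    if not coords:
        coords, weights = [(0.0, 0.0)], [0.0]
    sigma = params.sigma if params.sigma is not None else 0.3 * layout.median_bond_length
    xmin, ymin, xmax, ymax = layout.extent
    extent = (
        xmin - params.padding,
        ymin - params.padding,
        xmax + params.padding,
        ymax + params.padding,
    )
    return heatmap_grid(np.array(coords), np.array(weights), sigma, params.ppu, extent)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _heat_to_rgba(grid: HeatmapGrid, params: RenderParams) -> Image.Image:
    v = grid.values
    peak = np.abs(v).max()
    h, w = v.shape
    rgba = np.zeros((h, w, 4), dtype=np.uint8)
    if peak > 0:
        norm = v / peak
        alpha = np.round(np.abs(norm) * params.alpha_max).astype(np.uint8)
        pos = norm > 0
        for c in range(3):
            rgba[..., c] = np.where(pos, params.positive_color[c], params.negative_color[c])
        rgba[..., 3] = alpha
    # row 0 of the value grid is ymin; images have y down
    return Image.fromarray(rgba[::-1], mode="RGBA")


def _draw_molecules(img: Image.Image, layout: DepictionLayout, params: RenderParams) -> None:
    draw = ImageDraw.Draw(img)
    ppu = params.ppu * params.upscale
    xmin = layout.extent[0] - params.padding
    ymax = layout.extent[3] + params.padding

    def to_px(p):
        return ((p[0] - xmin) * ppu, (ymax - p[1]) * ppu)

    black = (30, 30, 30, 255)
    for ml in layout.molecules:
        for a, b, order in ml.bonds:
            pa, pb = ml.coords[a], ml.coords[b]
            d = pb - pa
            n = np.array([-d[1], d[0]])
            nl = np.linalg.norm(n)
            n = n / nl * 0.08 if nl else n
            lines = {1.0: [0.0], 1.5: [0.0, 1.0], 2.0: [-1.0, 1.0], 3.0: [-1.0, 0.0, 1.0]}.get(
                order, [0.0]
            )
            for off in lines:
                draw.line(
                    [to_px(pa + n * off), to_px(pb + n * off)],
                    fill=black,
                    width=max(1, params.upscale),
                )
        for i, sym in enumerate(ml.symbols):
            if sym == "C" and ml.charges[i] == 0:
                continue
            label = sym + ({1: "+", -1: "-"}.get(ml.charges[i], "") if ml.charges[i] else "")
            px, py = to_px(ml.coords[i])
            r = 0.28 * ppu
            draw.ellipse([px - r, py - r, px + r, py + r], fill=(255, 255, 255, 255))
            draw.text((px, py), label, fill=black, anchor="mm")
    # arrow
    x0, x1, y = layout.arrow
    p0, p1 = to_px((x0, y)), to_px((x1, y))
    draw.line([p0, p1], fill=black, width=max(1, params.upscale))
    head = 0.25 * ppu
    draw.polygon(
        [(p1[0], p1[1]), (p1[0] - head, p1[1] - head * 0.6), (p1[0] - head, p1[1] + head * 0.6)],
        fill=black,
    )


def _render(
    layout: DepictionLayout,
    grid: Optional[HeatmapGrid],
    params: RenderParams,
    fmt: str,
) -> bytes:
    ppu = params.ppu * params.upscale
    xmin = layout.extent[0] - params.padding
    xmax = layout.extent[2] + params.padding
    ymin = layout.extent[1] - params.padding
    ymax = layout.extent[3] + params.padding
    W = int(round((xmax - xmin) * ppu)) + params.upscale
    H = int(round((ymax - ymin) * ppu)) + params.upscale
    img = Image.new("RGBA", (W, H), (255, 255, 255, 255))
    if grid is not None and np.abs(grid.values).max() > 0:
        heat = _heat_to_rgba(grid, params)
        heat = heat.resize(
            (heat.width * params.upscale, heat.height * params.upscale),
            resample=Image.NEAREST,
        )
        img.alpha_composite(heat, dest=(0, 0))
    _draw_molecules(img, layout, params)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    png = buf.getvalue()
    if fmt == "png":
        return png
    if fmt == "svg":
        b64 = base64.b64encode(png).decode("ascii")
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{W}" height="{H}">'
            f'<image width="{W}" height="{H}" '
            f'href="data:image/png;base64,{b64}"/></svg>'
        )
        return svg.encode("utf-8")
    raise InputError(f"unknown output format {fmt!r}")


def render_reaction(record: ReactionRecord | str, params: Optional[RenderParams] = None,
                    fmt: str = "png") -> bytes:
    """Plain reaction depiction with no heat-map layer."""
    if params is None:
        params = RenderParams()
    return _render(layout_reaction(record), None, params, fmt)


def render_explanation(
    record: ReactionRecord | str,
    explanation: dict,
    params: Optional[RenderParams] = None,
    entry: int = 0,
    fmt: str = "png",
) -> bytes:
    """Render one explanation entry of the explanation-JSON contract.

    The heat layer is rasterised at ``ppu`` and nearest-neighbour upscaled;
    the molecule drawing goes on top.  Zero weights produce a fully
    transparent layer, i.e. the plain depiction.
    """
    if params is None:
        params = RenderParams()
    smiles = record if isinstance(record, str) else record.reaction_smiles
    if explanation.get("reaction_smiles") != smiles:
        raise InputError("explanation does not reference this reaction")
    entries = explanation.get("explanations", [])
    if not 0 <= entry < len(entries):
        raise InputError(f"explanation entry {entry} out of range")
    atom_weights = {
        (a["molecule"], a["atom"]): float(a["weight"]) for a in entries[entry]["atoms"]
    }
    layout = layout_reaction(record)
    normalised = normalize_atom_weights(atom_weights)
    grid = heatmap_for_layout(layout, normalised, params) if normalised else None
    return _render(layout, grid, params, fmt)


def absent_fragment_report(
    absent_fragments: Sequence, top_k: int = 10
) -> list[dict]:
    """Top-k absent fragments by |weight|, ties broken by bit ascending."""
    rows = sorted(absent_fragments, key=lambda a: (-abs(a.weight), a.bit))[:top_k]
    return [
        {"bit": a.bit, "weight": a.weight, "candidates": list(a.candidates)}
        for a in rows
    ]
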