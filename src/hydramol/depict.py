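"""2D molecule depictions with per-atom strength highlights.

Donor hydrogens are shaded on a white-to-red gradient and acceptor atoms on
a white-to-blue gradient, with colour intensity monotone in strength and
optional 2-decimal numeric labels — a visual strength map of the molecule.
Output is SVG, byte-identical for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .exceptions import HydramolError
from .io import MoleculeRecord
from .strengths import StrengthSet

_WHITE = (1.0, 1.0, 1.0)
_RED = (0.86, 0.08, 0.10)
_BLUE = (0.13, 0.30, 0.85)


@dataclass(frozen=True)
class DepictionSpec:
    """Rendering options for strength depictions."""

    mode: str = "both"                 # donor | acceptor | both
    donor_palette: tuple = (_WHITE, _RED)
    acceptor_palette: tuple = (_WHITE, _BLUE)
    scale_max: float = 1.5             # strength mapped to full intensity
    annotate: bool = True
    width: int = 450
    height: int = 400

    def __post_init__(self) -> None:
        if self.mode not in ("donor", "acceptor", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")


def _blend(palette: tuple, fraction: float) -> tuple:
    lo, hi = palette
    f = min(max(fraction, 0.0), 1.0)
    return tuple(l + f * (h - l) for l, h in zip(lo, hi))


def highlight_colour(strength: float, scale_max: float, palette: tuple) -> tuple:
    """Colour whose distance from white grows monotonically with strength."""
    return _blend(palette, max(strength, 0.0) / scale_max)


def render_strengths(
    record: MoleculeRecord,
    strengths: StrengthSet,
    spec: DepictionSpec = DepictionSpec(),
) -> str:
    """Render one molecule as an SVG document with strength highlights."""
    mol = Chem.Mol(record.mol)
    try:
        rdDepictor.Compute2DCoords(mol)
    except Exception as exc:  # pragma: no cover - rdkit failure path
        raise HydramolError(f"{record.identifier}: cannot lay out molecule") from exc

    highlights: dict[int, tuple] = {}
    if spec.mode in ("donor", "both"):
        for idx, sd in strengths.donor.items():
            highlights[idx] = highlight_colour(sd, spec.scale_max, spec.donor_palette)
            if spec.annotate:
                mol.GetAtomWithIdx(idx).SetProp("atomNote", f"{sd:.2f}")
    if spec.mode in ("acceptor", "both"):
        for idx, sa in strengths.acceptor.items():
            highlights[idx] = highlight_colour(sa, spec.scale_max, spec.acceptor_palette)
            if spec.annotate:
                mol.GetAtomWithIdx(idx).SetProp("atomNote", f"{sa:.2f}")

    drawer = rdMolDraw2D.MolDraw2DSVG(spec.width, spec.height)
    opts = drawer.drawOptions()
    opts.addStereoAnnotation = False
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        mol,
        highlightAtoms=sorted(highlights),
        highlightAtomColors=highlights,
        highlightBonds=[],
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def render_to_file(
    record: MoleculeRecord,
    strengths: StrengthSet,
    path: str | Path,
    spec: DepictionSpec = DepictionSpec(),
) -> Path:
    path = Path(path)
    path.write_text(render_strengths(record, strengths, spec))
    return path


def write_index_page(paths: list[Path], out: str | Path) -> Path:
    """Batch index: a minimal SVG-linking HTML-free markdown list."""
    out = Path(out)
    lines = ["# Strength depictions", ""]
    lines += [f"- [{p.stem}]({p.name})" for p in paths]
    out.write_text("\n".join(lines) + "\n")
    return out
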