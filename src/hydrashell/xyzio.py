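"""Standard / extended XYZ reading and writing for ion–water clusters.

The comment line carries metadata as whitespace-separated ``key=value``
pairs (extended-XYZ style).  On writing, atoms are ordered Ca, then
O,H,H per water with fixed 8-decimal formatting, so identical inputs
produce byte-identical files.  On reading, any atom order is accepted:
hydrogens are grouped with their nearest oxygen.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .geometry import ClusterGeometry, WaterMolecule

__all__ = ["read_xyz", "write_xyz", "XYZParseError"]


class XYZParseError(ValueError):
    """Malformed XYZ content; the message names the offending line."""


def _parse_metadata(comment: str) -> dict:
    meta: dict = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, raw = token.partition("=")
        try:
            meta[key] = int(raw)
        except ValueError:
            try:
                meta[key] = float(raw)
            except ValueError:
                meta[key] = raw
    return meta


def read_xyz(path: str | Path) -> tuple[ClusterGeometry, dict]:
    """Parse an (extended-)XYZ cluster file.

    The single Ca atom is the ion; every H is assigned to its nearest O
    and each O must end up with exactly two hydrogens.  Returns the
    geometry plus the comment-line metadata dict (values parsed to
    int/float where possible).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}, line 1: expected an atom count")
    if len(lines) < 2 + natoms:
        raise XYZParseError(
            f"{path}: header promises {natoms} atoms, file has {len(lines) - 2} atom lines"
        )
    meta = _parse_metadata(lines[1] if len(lines) > 1 else "")
    elements: list[str] = []
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        lineno = 3 + i
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}, line {lineno}: expected 'El x y z'")
        elements.append(parts[0])
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}, line {lineno}: non-numeric coordinate")

    ca = [i for i, el in enumerate(elements) if el == "Ca"]
    if len(ca) != 1:
        raise XYZParseError(
            f"{path}: expected exactly one Ca atom, found {len(ca)}"
        )
    o_idx = [i for i, el in enumerate(elements) if el == "O"]
    h_idx = [i for i, el in enumerate(elements) if el == "H"]
    other = set(range(natoms)) - set(ca) - set(o_idx) - set(h_idx)
    if other:
        bad = sorted(other)[0]
        raise XYZParseError(
            f"{path}, line {3 + bad}: unsupported element {elements[bad]!r}"
        )
    if len(h_idx) != 2 * len(o_idx):
        raise XYZParseError(
            f"{path}: {len(o_idx)} O need {2 * len(o_idx)} H, found {len(h_idx)}"
        )
    assigned: dict[int, list[int]] = {i: [] for i in o_idx}
    for h in h_idx:
        nearest = min(o_idx, key=lambda o: float(np.linalg.norm(coords[h] - coords[o])))
        assigned[nearest].append(h)
    for o, hs in assigned.items():
        if len(hs) != 2:
            raise XYZParseError(
                f"{path}, line {3 + o}: O has {len(hs)} nearest hydrogens, expected 2"
            )
    waters = tuple(
        WaterMolecule(coords[o], coords[assigned[o]]) for o in o_idx
    )
    charge = int(meta.get("ion_charge", 2))
    return ClusterGeometry(coords[ca[0]], charge, waters), meta


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v).lower()
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.6f}"
    return str(v)


def write_xyz(
    geometry: ClusterGeometry,
    path: str | Path,
    metadata: Mapping | None = None,
) -> Path:
    """Write a cluster as extended XYZ (Ca first, then O,H,H per water)."""
    path = Path(path)
    comment = " ".join(
        f"{k}={_format_value(v)}" for k, v in (metadata or {}).items()
    )
    lines = [str(geometry.n_atoms), comment]
    def fmt(el: str, p: np.ndarray) -> str:
        return f"{el:2s} {p[0]:16.8f} {p[1]:16.8f} {p[2]:16.8f}"
    lines.append(fmt("Ca", geometry.ion_position))
    for w in geometry.waters:
        lines.append(fmt("O", w.oxygen))
        lines.append(fmt("H", w.hydrogens[0]))
        lines.append(fmt("H", w.hydrogens[1]))
    path.write_text("\n".join(lines) + "\n")
    return path
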