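"""Contour-file readers and writers.

Two on-disk dialects:

* JSON — a list of per-section records
  ``{"z_mm": z, "lumen": [[x, y], ...], "outer_wall": [...], "lrncs": [[...], ...]}``
* CSV — long format with columns
  ``section_id, structure, ring_index, x_mm, y_mm``
  where ``structure`` is ``lumen``, ``outer_wall`` or ``lrnc`` and
  ``ring_index`` distinguishes multiple LRNCs (0 for lumen/outer wall).

Round-trips are lossless to well below 1e-6 mm (JSON stores full-precision
floats, CSV uses 8 decimals).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Contour, CrossSection, PlaqueModel3D


def sections_to_records(sections) -> list:
    recs = []
    for s in sections:
        recs.append({
            "z_mm": float(s.z),
            "lumen": s.lumen.vertices.tolist(),
            "outer_wall": s.outer_wall.vertices.tolist(),
            "lrncs": [c.vertices.tolist() for c in s.lrncs],
        })
    return recs


def records_to_sections(recs) -> list:
    out = []
    for r in recs:
        out.append(CrossSection(
            z=float(r["z_mm"]),
            lumen=Contour(np.asarray(r["lumen"], dtype=float)),
            outer_wall=Contour(np.asarray(r["outer_wall"], dtype=float)),
            lrncs=tuple(Contour(np.asarray(v, dtype=float)) for v in r["lrncs"]),
        ))
    return out


def save_contours_json(sections, path) -> None:
    Path(path).write_text(json.dumps(sections_to_records(sections)))


def load_contours_json(path) -> list:
    return records_to_sections(json.loads(Path(path).read_text()))


def save_contours_csv(sections, path) -> None:
    rows = []
    for sid, s in enumerate(sections):
        structures = [("lumen", 0, s.lumen), ("outer_wall", 0, s.outer_wall)]
        structures += [("lrnc", i, c) for i, c in enumerate(s.lrncs)]
        for name, ring, c in structures:
            for x, y in c.vertices:
                rows.append((sid, s.z, name, ring, x, y))
    df = pd.DataFrame(rows, columns=["section_id", "z_mm", "structure",
                                     "ring_index", "x_mm", "y_mm"])
    df.to_csv(path, index=False, float_format="%.8f")


def load_contours_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("section_id"):
        z = float(g["z_mm"].iloc[0])
        def verts(sub):
            return np.column_stack([sub["x_mm"].to_numpy(), sub["y_mm"].to_numpy()])
        lum = Contour(verts(g[g.structure == "lumen"]))
        outw = Contour(verts(g[g.structure == "outer_wall"]))
        lrncs = []
        for _, gg in g[g.structure == "lrnc"].groupby("ring_index"):
            lrncs.append(Contour(verts(gg)))
        out.append(CrossSection(z, lum, outw, tuple(lrncs)))
    return out


def save_model(model: PlaqueModel3D, path) -> None:
    save_contours_json(model.base_sections, path)


def load_model(path, match: bool = False) -> PlaqueModel3D:
    sections = load_contours_json(path)
    return PlaqueModel3D.from_sections(sections, match=match)
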