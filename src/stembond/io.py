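"""Readers and writers for the package's plain-text file dialects.

All tables are TSV.  Provenance lines start with ``#`` and hold ``key=value``
pairs; they never include timestamps, so re-running a study with the same
configuration reproduces every output byte for byte.

Force-curve dialect (one file per curve)::

    # curve_id=c001
    # sample_id=gel1
    # probe=anti_FN
    # substrate=stembond_soft
    # spring_constant_N_per_m=0.05
    # bead_radius_um=18.64
    segment	piezo_height_nm	force_pN
    approach	0	-1.2109...
    ...

Floats are written with ``repr`` precision so read/write round-trips are
lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .forcecurve import ForceCurve, Segment
from .tethering import DensityGrid, EventSet, RuptureEvent, SignificanceMask

__all__ = [
    "read_force_curve",
    "write_force_curve",
    "read_event_table",
    "write_event_table",
    "read_expression_table",
    "write_tsv",
    "write_grid",
    "write_mask",
]

_FLOAT_FMT = "%.17g"


def write_force_curve(curve: ForceCurve, path) -> None:
    path = Path(path)
    lines = [
        f"# curve_id={curve.curve_id}",
        f"# sample_id={curve.sample_id}",
        f"# probe={curve.probe}",
        f"# substrate={curve.substrate}",
        f"# spring_constant_N_per_m={curve.spring_constant!r}",
    ]
    if curve.bead_radius_um is not None:
        lines.append(f"# bead_radius_um={curve.bead_radius_um!r}")
    lines.append("segment\tpiezo_height_nm\tforce_pN")
    for seg in curve.segments:
        for z, f in zip(seg.piezo_height_nm, seg.force_pN):
            lines.append(f"{seg.label}\t{float(z)!r}\t{float(f)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_force_curve(path) -> ForceCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            if body_lines:
                raise ValueError(f"{path}:{lineno}: header line after table body")
            stripped = line.lstrip("#").strip()
            if "=" not in stripped:
                raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, value = stripped.partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    required = ("curve_id", "sample_id", "probe", "substrate", "spring_constant_N_per_m")
    for key in required:
        if key not in meta:
            raise ValueError(f"{path}: missing required header key {key!r}")
    body = pd.read_csv(
        _io.StringIO("\n".join(body_lines)), sep="\t", float_precision="round_trip"
    )
    segments = []
    for label in body["segment"].unique():
        rows = body[body["segment"] == label]
        segments.append(
            Segment(
                label=label,
                piezo_height_nm=rows["piezo_height_nm"].to_numpy(dtype=float),
                force_pN=rows["force_pN"].to_numpy(dtype=float),
            )
        )
    return ForceCurve(
        curve_id=meta["curve_id"],
        sample_id=meta["sample_id"],
        probe=meta["probe"],
        substrate=meta["substrate"],
        spring_constant=float(meta["spring_constant_N_per_m"]),
        bead_radius_um=float(meta["bead_radius_um"]) if "bead_radius_um" in meta else None,
        segments=tuple(segments),
    )


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a DataFrame as TSV with optional '#'-prefixed provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_event_table(event_sets: list[EventSet], path, provenance: dict | None = None) -> None:
    rows = [
        {
            "curve_id": ev.curve_id,
            "sample_id": es.sample_id,
            "probe": es.probe,
            "substrate": es.substrate,
            "rupture_force_pN": ev.rupture_force_pN,
            "rupture_length_nm": ev.rupture_length_nm,
            "n_curves_total": es.n_curves_total,
        }
        for es in event_sets
        for ev in es.events
    ]
    columns = [
        "curve_id",
        "sample_id",
        "probe",
        "substrate",
        "rupture_force_pN",
        "rupture_length_nm",
        "n_curves_total",
    ]
    write_tsv(pd.DataFrame(rows, columns=columns), path, provenance)


def read_event_table(path) -> list[EventSet]:
    """Read an event TSV back into per-sample EventSets."""
    df = read_tsv(path)
    sets = []
    for (sample_id, probe, substrate), rows in df.groupby(
        ["sample_id", "probe", "substrate"], sort=True
    ):
        events = tuple(
            RuptureEvent(
                rupture_force_pN=r.rupture_force_pN,
                rupture_length_nm=r.rupture_length_nm,
                curve_id=str(r.curve_id),
            )
            for r in rows.itertuples()
        )
        n_total = int(rows["n_curves_total"].iloc[0]) if "n_curves_total" in rows else 0
        sets.append(
            EventSet(
                events=events,
                sample_id=str(sample_id),
                probe=str(probe),
                substrate=str(substrate),
                n_curves_total=max(n_total, len(events)),
            )
        )
    return sets


def read_expression_table(path) -> pd.DataFrame:
    from .signature import validate_expression_table

    return validate_expression_table(read_tsv(path))


def _matrix_frame(values: np.ndarray, row_edges: np.ndarray, col_edges: np.ndarray) -> pd.DataFrame:
    """Matrix as TSV with bin-edge headers: columns are col-bin intervals,
    first column the row-bin interval labels."""
    col_labels = [f"{float(lo)!r}..{float(hi)!r}" for lo, hi in zip(col_edges[:-1], col_edges[1:])]
    row_labels = [f"{float(lo)!r}..{float(hi)!r}" for lo, hi in zip(row_edges[:-1], row_edges[1:])]
    df = pd.DataFrame(values, columns=col_labels)
    df.insert(0, "length_bin_nm", row_labels)
    return df


def write_grid(grid: DensityGrid, path, provenance: dict | None = None) -> None:
    df = _matrix_frame(grid.density, grid.length_bin_edges_nm, grid.log10_force_bin_edges)
    prov = dict(provenance or {})
    prov["n_events"] = grid.n_events
    write_tsv(df, path, prov)


def write_mask(
    mask: SignificanceMask, grid: DensityGrid, path, provenance: dict | None = None
) -> None:
    df = _matrix_frame(
        mask.mask.astype(int), grid.length_bin_edges_nm, grid.log10_force_bin_edges
    )
    prov = dict(provenance or {})
    prov["kernel_size"] = mask.kernel_size
    write_tsv(df, path, prov)
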