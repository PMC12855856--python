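"""Readers and writers for every external representation the pipeline touches.

Units policy: RMSF values are kept in nm exactly as trajectory tools emit
them; coordinates and inter-residue distances are Å as deposited in PDB
files.  No conversion is ever performed implicitly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .residues import (
    DEFAULT_MUTATED_POSITIONS,
    HEAVY,
    PEPTIDE,
    ResidueKey,
    SequentialNumbering,
    make_label,
    parse_residue_key,
)

log = logging.getLogger(__name__)

CONDITIONS = ("V", "P")
PROVENANCES = ("crystal", "in_silico_mutant")


class RmsfParseError(ValueError):
    """Raised when an RMSF table cannot be parsed."""


class HarmonizationError(ValueError):
    """Raised when trajectories cannot be reconciled onto one residue set."""


class PdbError(ValueError):
    """Raised on malformed or incomplete PDB input."""


@dataclass
class RmsfProfile:
    """Per-residue RMSF magnitudes (nm) for a single trajectory."""

    trajectory_id: str
    copy_id: str
    condition: str  # 'V' or 'P'
    provenance: str  # 'crystal' or 'in_silico_mutant'
    values: dict[ResidueKey, float]
    identities: dict[ResidueKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be in {CONDITIONS}, got {self.condition!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be in {PROVENANCES}, got {self.provenance!r}")
        for key, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"RMSF for {key} must be finite and >= 0, got {v}")


@dataclass
class RmsfDataset:
    """Residues x trajectories RMSF matrix plus pairing metadata.

    ``pairs`` lists (trajectory_id_V, trajectory_id_P) tuples sharing a
    crystal copy; a complete dataset has exactly two profiles per copy, one
    per condition.
    """

    residues: list[ResidueKey]
    profiles: list[RmsfProfile]
    pairs: list[tuple[str, str]]
    labels: dict[ResidueKey, str] = field(default_factory=dict)

    @property
    def n_trajectories(self) -> int:
        return len(self.profiles)

    @property
    def matrix(self) -> np.ndarray:
        """(n_residues, n_trajectories) array of RMSF in nm."""
        return np.array(
            [[p.values[r] for p in self.profiles] for r in self.residues], dtype=float
        )

    def label(self, key: ResidueKey) -> str:
        return self.labels.get(key, str(key))

    def condition_indices(self, condition: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.profiles) if p.condition == condition])

    def paired_values(self, key: ResidueKey) -> tuple[np.ndarray, np.ndarray]:
        """RMSF of one residue as (V, P) arrays aligned by crystal copy."""
        by_id = {p.trajectory_id: p for p in self.profiles}
        v = np.array([by_id[a].values[key] for a, _ in self.pairs])
        p = np.array([by_id[b].values[key] for _, b in self.pairs])
        return v, p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=[str(r) for r in self.residues],
            columns=[p.trajectory_id for p in self.profiles],
        )


@dataclass
class CaCoordinates:
    """Cα positions (Å) for network nodes, from a reference structure."""

    positions: dict[ResidueKey, np.ndarray]
    source_id: str = ""

    def __post_init__(self) -> None:
        for key, pos in self.positions.items():
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"position for {key} must be a finite 3-vector")
            self.positions[key] = arr

    def distance(self, a: ResidueKey, b: ResidueKey) -> float:
        return float(np.linalg.norm(self.positions[a] - self.positions[b]))

    def missing(self, residues: Iterable[ResidueKey]) -> list[ResidueKey]:
        return [r for r in residues if r not in self.positions]

    def distance_matrix(self, residues: Sequence[ResidueKey]) -> np.ndarray:
        pts = np.array([self.positions[r] for r in residues])
        diff = pts[:, None, :] - pts[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


# ---------------------------------------------------------------------------
# RMSF tables (.xvg dialect of `gmx rmsf -res`, or plain two-column TSV)
# ---------------------------------------------------------------------------

def read_rmsf_xvg(
    path: str | Path,
    trajectory_id: str,
    copy_id: str,
    condition: str,
    provenance: str = "crystal",
    numbering: SequentialNumbering | None = None,
) -> RmsfProfile:
    """Read a per-residue RMSF table.

    Lines starting with '@' or '#' are headers/comments; data rows are
    whitespace-separated ``residue_number  rmsf_nm``.  ``numbering`` maps the
    flat file residue numbers onto chain-aware ResidueKeys; when omitted a
    189-residue (180 heavy + 9 peptide) layout is assumed.
    """
    path = Path(path)
    numbering = numbering or SequentialNumbering()
    values: dict[ResidueKey, float] = {}
    seen: set[int] = set()
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("@", "#")):
                continue
            fields = stripped.split()
            try:
                resnum = int(float(fields[0]))
                rmsf = float(fields[1])
            except (ValueError, IndexError) as exc:
                raise RmsfParseError(
                    f"{path}: non-numeric data row at line {lineno}: {stripped!r}"
                ) from exc
            if resnum in seen:
                raise RmsfParseError(f"{path}: duplicate residue number {resnum} at line {lineno}")
            seen.add(resnum)
            values[numbering.key_for(resnum)] = rmsf
            n_rows += 1
    if n_rows == 0:
        raise RmsfParseError(f"{path}: no data rows")
    return RmsfProfile(
        trajectory_id=trajectory_id,
        copy_id=copy_id,
        condition=condition,
        provenance=provenance,
        values=values,
    )


def harmonize_residues(
    profiles: Sequence[RmsfProfile],
    mutated_positions: Mapping[ResidueKey, tuple[str, ...]] | None = None,
) -> RmsfDataset:
    """Reconcile trajectory profiles onto a single unified residue set.

    Every profile must cover the identical ResidueKey set; positions listed in
    ``mutated_positions`` (default: peptide position 3, V/P) are allowed to
    differ in amino-acid identity between conditions and receive a merged
    label such as ``p3V/P``.  Pairs are assembled by crystal copy id; each
    copy must contribute exactly one profile per condition.

    Idempotent: harmonizing the profiles of an already-harmonized dataset
    reproduces it.
    """
    if not profiles:
        raise HarmonizationError("no profiles to harmonize")
    if mutated_positions is None:
        mutated_positions = DEFAULT_MUTATED_POSITIONS

    reference = sorted(profiles[0].values)
    ref_set = set(reference)
    for p in profiles:
        extra = set(p.values) - ref_set
        missing = ref_set - set(p.values)
        if extra or missing:
            detail = []
            if missing:
                detail.append(f"missing {sorted(str(r) for r in missing)}")
            if extra:
                detail.append(f"unexpected {sorted(str(r) for r in extra)}")
            raise HarmonizationError(
                f"trajectory {p.trajectory_id!r} does not match the reference "
                f"residue set: {'; '.join(detail)}"
            )

    labels: dict[ResidueKey, str] = {}
    for key in reference:
        observed = [p.identities.get(key, "") for p in profiles]
        observed = list(dict.fromkeys(i for i in observed if i))
        if key in mutated_positions:
            idents = observed or list(mutated_positions[key])
            labels[key] = make_label(key, idents)
        else:
            if len(set(observed)) > 1:
                raise HarmonizationError(
                    f"residue {key} has conflicting identities {observed} but is "
                    "not listed as a designed mutation site"
                )
            labels[key] = make_label(key, observed)

    by_copy: dict[str, dict[str, str]] = {}
    for p in profiles:
        slot = by_copy.setdefault(p.copy_id, {})
        if p.condition in slot:
            raise HarmonizationError(
                f"copy {p.copy_id!r} has more than one {p.condition} trajectory"
            )
        slot[p.condition] = p.trajectory_id
    pairs = []
    for copy_id in sorted(by_copy):
        slot = by_copy[copy_id]
        if set(slot) != set(CONDITIONS):
            raise HarmonizationError(
                f"copy {copy_id!r} lacks a complete V/P pair (has {sorted(slot)})"
            )
        pairs.append((slot["V"], slot["P"]))

    return RmsfDataset(residues=reference, profiles=list(profiles), pairs=pairs, labels=labels)


def write_rmsf_dataset_tsv(dataset: RmsfDataset, path: str | Path) -> None:
    """Residues x trajectories matrix as TSV at full float precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["residue"] + [p.trajectory_id for p in dataset.profiles])
        for key in dataset.residues:
            writer.writerow([str(key)] + [repr(float(p.values[key])) for p in dataset.profiles])


def read_rmsf_dataset_tsv(
    path: str | Path, manifest: Sequence[Mapping[str, str]]
) -> RmsfDataset:
    """Inverse of :func:`write_rmsf_dataset_tsv`; ``manifest`` supplies the
    per-trajectory metadata (trajectory_id, copy_id, condition, provenance).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta = {m["trajectory_id"]: m for m in manifest}
    profiles = []
    for traj_id in frame.columns:
        if traj_id not in meta:
            raise HarmonizationError(f"trajectory {traj_id!r} missing from manifest")
        m = meta[traj_id]
        values = {parse_residue_key(r): float(frame.loc[r, traj_id]) for r in frame.index}
        profiles.append(
            RmsfProfile(
                trajectory_id=traj_id,
                copy_id=m["copy_id"],
                condition=m["condition"],
                provenance=m.get("provenance", "crystal"),
                values=values,
            )
        )
    return harmonize_residues(profiles)


# ---------------------------------------------------------------------------
# PDB: fixed-column Cα reader and byte-preserving B-factor writer
# ---------------------------------------------------------------------------
# wwPDB v3.3 ATOM/HETATM columns (1-based, inclusive):
#   13-16 atom name, 17 altloc, 22 chain, 23-26 resseq, 31-54 x/y/z,
#   55-60 occupancy, 61-66 temperature factor.

def _atom_fields(line: str) -> dict:
    return {
        "name": line[12:16].strip(),
        "altloc": line[16],
        "chain": line[21],
        "resseq": int(line[22:26]),
        "xyz": np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])]),
        "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
    }


def read_ca_coordinates(
    path: str | Path,
    selection: Mapping[str, tuple[str, range]] | None = None,
    source_id: str = "",
) -> CaCoordinates:
    """Extract Cα coordinates (Å) from a PDB file.

    ``selection`` maps a PDB chain id to ``(chain_role, residue_range)``;
    default selects chain 'A' residues 1-180 as the heavy chain and chain 'C'
    residues 1-9 as the peptide.  When alternate locations exist the
    highest-occupancy one wins (ties: first encountered).  A selected residue
    with no CA atom raises :class:`PdbError`.
    """
    path = Path(path)
    if selection is None:
        selection = {"A": (HEAVY, range(1, 181)), "C": (PEPTIDE, range(1, 10))}
    best: dict[ResidueKey, tuple[float, np.ndarray]] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if line[12:16].strip() != "CA":
                continue
            f = _atom_fields(line)
            if f["chain"] not in selection:
                continue
            role, resrange = selection[f["chain"]]
            if f["resseq"] not in resrange:
                continue
            key = ResidueKey(role, f["resseq"])
            if key not in best or f["occupancy"] > best[key][0]:
                best[key] = (f["occupancy"], f["xyz"])
    expected = [
        ResidueKey(role, i) for role, rng in selection.values() for i in rng
    ]
    missing = [k for k in expected if k not in best]
    if missing:
        raise PdbError(
            f"{path}: no CA atom for selected residues "
            f"{[str(m) for m in missing[:10]]}{'...' if len(missing) > 10 else ''}"
        )
    return CaCoordinates(
        positions={k: xyz for k, (_occ, xyz) in best.items()},
        source_id=source_id or path.name,
    )


def write_node_values_pdb(
    template: str | Path,
    values: Mapping[ResidueKey, float],
    out_path: str | Path,
    selection: Mapping[str, tuple[str, range]] | None = None,
    sentinel: float = 0.0,
) -> None:
    """Write per-residue values into the B-factor column of a PDB template.

    Only columns 61-66 of ATOM/HETATM records change (fixed '%6.2f'); every
    other byte of the template is preserved.  Residues not covered by
    ``values`` receive ``sentinel``.
    """
    template = Path(template)
    if selection is None:
        selection = {"A": (HEAVY, range(1, 181)), "C": (PEPTIDE, range(1, 10))}
    out_lines = []
    with template.open() as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) >= 66:
                chain = line[21]
                resseq = int(line[22:26])
                value = sentinel
                if chain in selection:
                    role, rng = selection[chain]
                    if resseq in rng:
                        value = values.get(ResidueKey(role, resseq), sentinel)
                rendered = f"{value:6.2f}"
                if len(rendered) > 6:
                    raise ValueError(
                        f"value {value} overflows the 6-character B-factor field; "
                        "rescale values before writing"
                    )
                line = line[:60] + rendered + line[66:]
            out_lines.append(line)
    Path(out_path).write_text("".join(out_lines))


# ---------------------------------------------------------------------------
# Network files
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "rho", "abs_rho", "r_ca", "weight"]


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "edge_csv") -> None:
    """Persist a residue network.

    ``edge_csv`` writes ``<stem>.edges.csv`` + ``<stem>.nodes.csv`` (labels
    and Cα coordinates); ``graphml`` a single GraphML file.  Both round-trip
    losslessly through :func:`read_network`.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for node, data in graph.nodes(data=True):
            attrs = {"label": data.get("label", str(node))}
            if "pos" in data:
                attrs.update(x=float(data["pos"][0]), y=float(data["pos"][1]), z=float(data["pos"][2]))
            g.add_node(str(node), **attrs)
        for u, v, data in graph.edges(data=True):
            g.add_edge(str(u), str(v), **{k: float(data[k]) for k in ("rho", "abs_rho", "r_ca", "weight")})
        nx.write_graphml(g, path)
        return
    if fmt != "edge_csv":
        raise ValueError(f"unknown network format {fmt!r}")
    stem = path.with_suffix("") if path.suffix == ".csv" else path
    edge_rows = [
        {
            "source": str(u),
            "target": str(v),
            "rho": repr(d["rho"]),
            "abs_rho": repr(d["abs_rho"]),
            "r_ca": repr(d["r_ca"]),
            "weight": repr(d["weight"]),
        }
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    pd.DataFrame(edge_rows, columns=_EDGE_COLUMNS).to_csv(f"{stem}.edges.csv", index=False)
    node_rows = []
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        row = {"node": str(node), "label": data.get("label", str(node))}
        if "pos" in data:
            row.update(
                x=repr(float(data["pos"][0])),
                y=repr(float(data["pos"][1])),
                z=repr(float(data["pos"][2])),
            )
        node_rows.append(row)
    pd.DataFrame(node_rows, columns=["node", "label", "x", "y", "z"]).to_csv(
        f"{stem}.nodes.csv", index=False
    )


def read_network(path: str | Path, fmt: str = "edge_csv") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    g = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        for node, data in raw.nodes(data=True):
            key = parse_residue_key(node)
            attrs = {"label": data.get("label", node)}
            if "x" in data:
                attrs["pos"] = np.array([data["x"], data["y"], data["z"]], dtype=float)
            g.add_node(key, **attrs)
        for u, v, data in raw.edges(data=True):
            g.add_edge(
                parse_residue_key(u),
                parse_residue_key(v),
                **{k: float(data[k]) for k in ("rho", "abs_rho", "r_ca", "weight")},
            )
        return g
    stem = path.with_suffix("") if path.suffix == ".csv" else path
    nodes = pd.read_csv(f"{stem}.nodes.csv")
    for _, row in nodes.iterrows():
        key = parse_residue_key(row["node"])
        attrs = {"label": row["label"]}
        if not pd.isna(row.get("x")):
            attrs["pos"] = np.array([row["x"], row["y"], row["z"]], dtype=float)
        g.add_node(key, **attrs)
    edges = pd.read_csv(f"{stem}.edges.csv")
    for _, row in edges.iterrows():
        g.add_edge(
            parse_residue_key(row["source"]),
            parse_residue_key(row["target"]),
            rho=float(row["rho"]),
            abs_rho=float(row["abs_rho"]),
            r_ca=float(row["r_ca"]),
            weight=float(row["weight"]),
        )
    return g


def write_coordinates_pdb(coords: CaCoordinates, path: str | Path) -> None:
    """Write Cα-only coordinates as a minimal PDB file (heavy chain 'A',
    peptide chain 'C'), usable as a template for the B-factor writer."""
    chain_for = {HEAVY: "A", PEPTIDE: "C"}
    lines = []
    serial = 1
    for key in sorted(coords.positions):
        x, y, z = coords.positions[key]
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain_for[key.chain_role]}{key.position:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C  \n"
        )
        serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines))
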