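"""Sequence, trajectory and metrics I/O shared by all modules.

Formats: FASTA (single record) or raw strings for sequences; multi-model
PDB and plain XYZ for bead trajectories (one pseudo-atom named C1' per
nucleotide, chain A = Watson, chain B = Crick); multi-model PDB for
atomistic structures; YAML for run configs; CSV with metadata headers for
metrics tables.  Every written artifact carries a provenance block
(package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .dynamics import TrajectoryEnsemble
from .synthetic import AtomisticEnsemble, AtomisticStructure
from .topology import DuplexSequence, build_duplex_topology

__all__ = [
    "read_sequence",
    "write_bead_pdb",
    "read_bead_pdb",
    "write_xyz",
    "read_xyz",
    "write_atomistic_pdb",
    "write_metrics_csv",
    "read_config",
    "config_hash",
]


def read_sequence(source: str | Path, circular: bool = False) -> DuplexSequence:
    """A duplex sequence from a FASTA file path or a raw string.

    Circularity always comes from the flag, never from the file.  A string
    that points at an existing file is read as FASTA; anything else is
    treated as a literal sequence (case-insensitive).
    """
    path = Path(source)
    try:
        is_file = path.is_file()
    except OSError:
        is_file = False
    if is_file:
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single-record FASTA, got {len(records)} records "
                f"in {path}"
            )
        return DuplexSequence(str(records[0].seq).upper(), circular=circular)
    return DuplexSequence(str(source).upper(), circular=circular)


def config_hash(config: dict) -> str:
    """Short stable hash of a config dict, for provenance blocks."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_lines(provenance: dict) -> list[str]:
    lines = [f"REMARK 250 CGDNA VERSION {__version__}"]
    for key, val in provenance.items():
        lines.append(f"REMARK 250 {str(key).upper()}: {val}")
    return lines


_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_BASE_OF = {v: k for k, v in _RESNAME.items()}


def write_bead_pdb(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Multi-model PDB of a bead trajectory (3-decimal coordinates)."""
    topo = ensemble.topology
    if topo is None:
        raise ValueError("ensemble has no topology; cannot assign residues")
    n = topo.n_bp
    seq = topo.sequence
    lines = _provenance_lines(ensemble.provenance)
    for f, frame in enumerate(ensemble.frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for bead in range(2 * n):
            if bead < n:
                chain, resseq, base = "A", bead + 1, seq.watson[bead]
            else:
                q = bead - n
                chain, resseq, base = "B", q + 1, seq.crick[q]
            x, y, z = frame[bead]
            lines.append(
                f"ATOM  {serial:5d}  C1' {_RESNAME[base]:>3s} {chain}{resseq:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bead_pdb(path: str | Path, circular: bool = False) -> TrajectoryEnsemble:
    """Read a bead-dialect multi-model PDB back into an ensemble.

    Rejects files whose ATOM records are not C1' pseudo-atoms of the
    cgdna bead dialect, naming the first offending line.
    """
    frames: list[list[tuple[str, int, str, np.ndarray]]] = []
    current: list[tuple[str, int, str, np.ndarray]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            frames.append(current)
        elif rec == "ATOM":
            name = raw[12:16].strip()
            if name != "C1'":
                raise ValueError(
                    f"line {lineno}: unexpected atom name {name!r} "
                    "(bead dialect expects C1' pseudo-atoms)"
                )
            resname = raw[17:20].strip()
            if resname not in _BASE_OF:
                raise ValueError(
                    f"line {lineno}: unexpected residue name {resname!r}"
                )
            chain = raw[21]
            if chain not in "AB":
                raise ValueError(f"line {lineno}: unexpected chain {chain!r}")
            resseq = int(raw[22:26])
            xyz = np.array(
                [float(raw[30:38]), float(raw[38:46]), float(raw[46:54])]
            )
            current.append((chain, resseq, _BASE_OF[resname], xyz))
    if not frames:
        raise ValueError(f"{path}: no MODEL/ENDMDL frames found")
    first = frames[0]
    watson = sorted(
        [t for t in first if t[0] == "A"], key=lambda t: t[1]
    )
    crick = sorted([t for t in first if t[0] == "B"], key=lambda t: t[1])
    if len(watson) != len(crick):
        raise ValueError("strand bead counts differ")
    seq = DuplexSequence("".join(t[2] for t in watson), circular=circular)
    topo = build_duplex_topology(seq)
    coords = np.empty((len(frames), 2 * len(watson), 3))
    for f, frame in enumerate(frames):
        if len(frame) != 2 * len(watson):
            raise ValueError(f"frame {f} has inconsistent bead count")
        w = sorted([t for t in frame if t[0] == "A"], key=lambda t: t[1])
        c = sorted([t for t in frame if t[0] == "B"], key=lambda t: t[1])
        coords[f, : len(w)] = [t[3] for t in w]
        coords[f, len(w) :] = [t[3] for t in c]
    return TrajectoryEnsemble(
        frames=coords,
        times=np.arange(len(frames), dtype=float),
        topology=topo,
        provenance={"source": str(path)},
    )


def write_xyz(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Plain multi-frame XYZ (full float precision; one C atom per bead)."""
    lines = []
    n = ensemble.n_beads
    for f, frame in enumerate(ensemble.frames):
        lines.append(str(n))
        lines.append(
            f"cgdna beads frame {f} t={ensemble.times[f]!r} "
            f"version={__version__}"
        )
        for x, y, z in frame:
            lines.append(f"C {float(x)!r} {float(y)!r} {float(z)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(
    path: str | Path, sequence: DuplexSequence | None = None
) -> TrajectoryEnsemble:
    """Read a multi-frame XYZ written by :func:`write_xyz`."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        frames.append(
            np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        )
        i += 2 + n
    topo = build_duplex_topology(sequence) if sequence is not None else None
    return TrajectoryEnsemble(
        frames=np.stack(frames),
        times=np.arange(len(frames), dtype=float),
        topology=topo,
        provenance={"source": str(path)},
    )


def write_atomistic_pdb(
    ensemble_or_structure: AtomisticEnsemble | AtomisticStructure,
    path: str | Path,
) -> None:
    """Multi-model PDB of an atomistic structure or ensemble."""
    if isinstance(ensemble_or_structure, AtomisticStructure):
        struct = ensemble_or_structure
        frames = struct.coords[None]
    else:
        struct = ensemble_or_structure.structure
        frames = ensemble_or_structure.frames
    n_res = struct.n_residues
    n_bp = n_res // 2
    lines = _provenance_lines(struct.provenance)
    for f in range(len(frames)):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for a in range(struct.n_atoms):
            r = int(struct.residue_index[a])
            base = struct.residue_base[r]
            if r < n_bp:
                chain, resseq = "A", r + 1
            else:
                chain, resseq = "B", r - n_bp + 1
            name = struct.atom_names[a]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = frames[f, a]
            element = name[0]
            lines.append(
                f"ATOM  {serial % 100000:5d} {pdb_name:>4s} {_RESNAME[base]:>3s} "
                f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"           {element}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_atomistic_pdb(
    path: str | Path, circular: bool = False
) -> AtomisticEnsemble:
    """Read a multi-model atomistic PDB in the package's own dialect.

    The atom layout must match the package's nucleotide templates (same
    atom names per residue); the first non-conforming line is reported.
    """
    from .synthetic import _structure_layout

    model_coords: list[np.ndarray] = []
    current: list[np.ndarray] = []
    records: list[tuple[str, int, str, str]] = []  # chain, resseq, resname, atom
    first_model = True
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            model_coords.append(np.array(current))
            first_model = False
        elif rec == "ATOM":
            name = raw[12:16].strip()
            resname = raw[17:20].strip()
            if resname not in _BASE_OF:
                raise ValueError(
                    f"line {lineno}: unexpected residue name {resname!r}"
                )
            if first_model:
                records.append((raw[21], int(raw[22:26]), resname, name))
            current.append(
                np.array([float(raw[30:38]), float(raw[38:46]), float(raw[46:54])])
            )
    if not model_coords:
        raise ValueError(f"{path}: no MODEL/ENDMDL frames found")
    watson = [r for r in records if r[0] == "A"]
    seq_bases = []
    seen = set()
    for chain, resseq, resname, _name in watson:
        if resseq not in seen:
            seen.add(resseq)
            seq_bases.append(_BASE_OF[resname])
    seq = DuplexSequence("".join(seq_bases), circular=circular)
    atom_names, residue_index, bases, bonds = _structure_layout(seq)
    if len(records) != len(atom_names):
        raise ValueError(
            f"{path}: {len(records)} atoms do not match the template layout "
            f"({len(atom_names)} atoms for this sequence)"
        )
    for k, ((_c, _r, _rn, name), expect) in enumerate(zip(records, atom_names)):
        if name != expect:
            raise ValueError(
                f"atom {k + 1}: name {name!r} does not match the template "
                f"layout (expected {expect!r})"
            )
    frames = np.stack(model_coords)
    structure = AtomisticStructure(
        sequence=seq,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_base=bases,
        coords=frames[0].copy(),
        bonds=bonds,
        provenance={"source": str(path)},
    )
    return AtomisticEnsemble(structure=structure, frames=frames)


def write_metrics_csv(
    path: str | Path, table: dict[str, np.ndarray | list], metadata: dict
) -> None:
    """CSV with ``# key: value`` metadata headers above the column block."""
    import pandas as pd

    header = [f"# cgdna version: {__version__}"]
    header += [f"# {k}: {v}" for k, v in metadata.items()]
    df = pd.DataFrame(table)
    Path(path).write_text("\n".join(header) + "\n" + df.to_csv(index=False))


def read_config(path: str | Path) -> dict:
    """YAML run config."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
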