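"""Regression back-mapping from C1' beads to all-atom coordinates.

Reconstruction runs in two stages over sliding 10-bp windows, in the
GLIMPS lineage of local linear decoder models:

1. **Backbone stage** (sequence-neutral): for every 10-bp window the 20
   bead coordinates, superposed onto a canonical window frame, predict the
   backbone heavy atoms (sugar + phosphate) of the 20 nucleotides through
   one shared ordinary-least-squares map (optionally PCA rank-reduced).
   Overlapping window predictions are blended by uniform averaging in the
   global frame.
2. **Base stage** (bp-class dependent): for each base pair, the backbone
   atoms of its two nucleotides, superposed onto a canonical purine-first
   bp frame, predict the base heavy atoms through one map per bp class
   (A·T/T·A share one model, G·C/C·G the other; pyrimidine-first pairs are
   swapped into the canonical orientation before encoding).

Working in superposed local frames makes the reconstruction equivariant
under rigid motion of the input beads.  A final soft-sphere steepest
descent (:func:`relax_clashes`) removes residual steric clashes — a
geometric clean-up, not a force-field minimisation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .analysis import kabsch_rotation
from .dynamics import TrajectoryEnsemble
from .synthetic import (
    AtomisticEnsemble,
    AtomisticStructure,
    BACKBONE_ATOMS,
    BASE_ATOMS,
    DuplexSequence,
    HelixSpec,
    _structure_layout,
    ideal_bdna_atomistic,
    ideal_bdna_beads,
)

__all__ = [
    "BackmapModel",
    "StericSettings",
    "train_backmap",
    "reconstruct",
    "relax_clashes",
]

logger = logging.getLogger("cgdna.backmap")

_PURINES = "AG"


def _bp_class(watson_base: str) -> str:
    """Canonical bp class: 'AT' for A·T/T·A, 'GC' for G·C/C·G."""
    return "AT" if watson_base in "AT" else "GC"


def _superpose_onto(mobile: np.ndarray, template: np.ndarray):
    """Centre + rotate mobile onto the centred template; returns the local
    coordinates and the (rotation, centroid) needed to go back."""
    cen = mobile.mean(axis=0)
    rot = kabsch_rotation(mobile - cen, template)
    local = (mobile - cen) @ rot.T
    return local, rot, cen


@dataclass
class BackmapModel:
    """Trained two-stage back-map regressions with frame conventions.

    ``backbone_w`` maps the flattened local window bead coordinates
    (augmented with 1) to local backbone-atom coordinates; ``base_w`` maps
    per-class local backbone-pair coordinates to base-atom coordinates.
    Templates store the canonical (centred) frames the Kabsch superposition
    targets.  Serialisation through :meth:`to_json` is lossless.
    """

    window: int
    bead_template: np.ndarray  # (2*window, 3) centred canonical bead frame
    backbone_w: np.ndarray  # (6*window + 1, 33*window... ) regression matrix
    base_templates: dict[str, np.ndarray] = field(default_factory=dict)
    base_w: dict[str, np.ndarray] = field(default_factory=dict)
    rank: int | None = None
    pca_components: np.ndarray | None = None  # (rank, 6*window)
    pca_mean: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "format": "cgdna-backmap",
            "version": 1,
            "window": self.window,
            "bead_template": self.bead_template.tolist(),
            "backbone_w": self.backbone_w.tolist(),
            "base_templates": {k: v.tolist() for k, v in self.base_templates.items()},
            "base_w": {k: v.tolist() for k, v in self.base_w.items()},
            "rank": self.rank,
            "pca_components": None
            if self.pca_components is None
            else self.pca_components.tolist(),
            "pca_mean": None if self.pca_mean is None else self.pca_mean.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "BackmapModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "cgdna-backmap":
            raise ValueError("not a cgdna back-map model file")
        return cls(
            window=d["window"],
            bead_template=np.array(d["bead_template"]),
            backbone_w=np.array(d["backbone_w"]),
            base_templates={k: np.array(v) for k, v in d["base_templates"].items()},
            base_w={k: np.array(v) for k, v in d["base_w"].items()},
            rank=d["rank"],
            pca_components=None
            if d["pca_components"] is None
            else np.array(d["pca_components"]),
            pca_mean=None if d["pca_mean"] is None else np.array(d["pca_mean"]),
            metadata=d["metadata"],
        )

    # -- feature transform -------------------------------------------------
    def _features(self, local_beads: np.ndarray) -> np.ndarray:
        x = local_beads.reshape(-1)
        if self.pca_components is not None:
            x = (x - self.pca_mean) @ self.pca_components.T
        return np.append(x, 1.0)


def _window_beads(frames: np.ndarray, n_bp: int, w0: int, window: int) -> np.ndarray:
    """Bead block of a window: Watson beads w0..w0+window-1 followed by the
    paired Crick beads in bp order; wraps for circular inputs."""
    bps = np.arange(w0, w0 + window) % n_bp
    watson = bps
    crick = 2 * n_bp - 1 - bps
    idx = np.concatenate([watson, crick])
    return frames[..., idx, :]


def _backbone_indices(structure_layout, n_bp: int, w0: int, window: int) -> np.ndarray:
    """Atom indices of the backbone atoms of a window's 2*window residues."""
    atom_names, residue_index, _bases, _bonds = structure_layout
    bps = np.arange(w0, w0 + window) % n_bp
    residues = np.concatenate([bps, 2 * n_bp - 1 - bps])
    idx = []
    names = np.array(atom_names)
    for r in residues:
        sel = np.where(residue_index == r)[0]
        nm = {names[i]: i for i in sel}
        idx.extend(nm[a] for a in BACKBONE_ATOMS)
    return np.array(idx, dtype=np.intp)


def train_backmap(
    bead_ensemble: TrajectoryEnsemble,
    atom_ensemble: AtomisticEnsemble,
    window: int = 10,
    rank: int | None = None,
) -> BackmapModel:
    """Train the two-stage back-map on paired bead/atom ensembles.

    The bead frames must be the exact C1' subsets of the atom frames (same
    frame order).  Every sliding ``window``-bp block of every frame is one
    backbone-stage sample; every bp of every frame is one base-stage sample
    of its bp class.  Raises if the sample count cannot support the
    regression rank.
    """
    seq = bead_ensemble.topology.sequence
    n_bp = len(seq)
    if n_bp < window:
        raise ValueError(f"need at least {window} bp, got {n_bp}")
    beads = bead_ensemble.frames
    atoms = atom_ensemble.frames
    if len(beads) != len(atoms):
        raise ValueError("bead and atom ensembles must have matching frames")
    struct = atom_ensemble.structure
    layout = (struct.atom_names, struct.residue_index, struct.residue_base, struct.bonds)

    # canonical frames from an ideal build
    ideal_beads = ideal_bdna_beads(DuplexSequence("A" * window), HelixSpec())
    bead_template = ideal_beads - ideal_beads.mean(axis=0)

    n_windows = n_bp - window + 1 if not seq.circular else n_bp
    n_feat = 6 * window
    n_samples = n_windows * len(beads)
    eff_rank = rank if rank is not None else n_feat
    if n_samples < eff_rank + 1:
        raise ValueError(
            f"{n_samples} samples cannot support a rank-{eff_rank} regression; "
            "provide more frames or a stronger rank reduction"
        )

    xs = np.empty((n_samples, n_feat))
    ys = np.empty((n_samples, 2 * window * len(BACKBONE_ATOMS) * 3))
    row = 0
    for w0 in range(n_windows):
        bb_idx = _backbone_indices(layout, n_bp, w0, window)
        wb = _window_beads(beads, n_bp, w0, window)  # (F, 2w, 3)
        for f in range(len(beads)):
            local, rot, cen = _superpose_onto(wb[f], bead_template)
            xs[row] = local.reshape(-1)
            ys[row] = ((atoms[f, bb_idx] - cen) @ rot.T).reshape(-1)
            row += 1

    pca_components = pca_mean = None
    if rank is not None and rank < n_feat:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=rank)
        xs_red = pca.fit_transform(xs)
        pca_components = pca.components_
        pca_mean = pca.mean_
        design = np.column_stack([xs_red, np.ones(len(xs_red))])
    else:
        design = np.column_stack([xs, np.ones(len(xs))])
    backbone_w, *_ = np.linalg.lstsq(design, ys, rcond=None)

    model = BackmapModel(
        window=window,
        bead_template=bead_template,
        backbone_w=backbone_w,
        rank=rank,
        pca_components=pca_components,
        pca_mean=pca_mean,
        metadata={
            "n_frames": len(beads),
            "n_windows": n_windows,
            "training_sequence": seq.watson,
        },
    )

    # base stage: one model per bp class, purine-first orientation
    ideal = ideal_bdna_atomistic(DuplexSequence("AGAG"), HelixSpec())
    class_templates: dict[str, np.ndarray] = {}
    for cls, bp_pos in (("AT", 0), ("GC", 1)):
        res_w, res_c = bp_pos, 2 * 4 - 1 - bp_pos
        idx = np.concatenate(
            [ideal.atom_indices(res_w, BACKBONE_ATOMS),
             ideal.atom_indices(res_c, BACKBONE_ATOMS)]
        )
        block = ideal.coords[idx]
        class_templates[cls] = block - block.mean(axis=0)

    samples_x: dict[str, list[np.ndarray]] = {"AT": [], "GC": []}
    samples_y: dict[str, list[np.ndarray]] = {"AT": [], "GC": []}
    for p in range(n_bp):
        wbase = seq.watson[p]
        cls = _bp_class(wbase)
        res_w, res_c = p, 2 * n_bp - 1 - p
        # purine first
        if wbase in _PURINES:
            first, second = res_w, res_c
            pur_base, pyr_base = wbase, seq.crick[n_bp - 1 - p]
        else:
            first, second = res_c, res_w
            pur_base, pyr_base = seq.crick[n_bp - 1 - p], wbase
        bb_idx = np.concatenate(
            [struct.atom_indices(first, BACKBONE_ATOMS),
             struct.atom_indices(second, BACKBONE_ATOMS)]
        )
        base_idx = np.concatenate(
            [struct.atom_indices(first, BASE_ATOMS[pur_base]),
             struct.atom_indices(second, BASE_ATOMS[pyr_base])]
        )
        for f in range(len(atoms)):
            local, rot, cen = _superpose_onto(atoms[f, bb_idx], class_templates[cls])
            samples_x[cls].append(local.reshape(-1))
            samples_y[cls].append(((atoms[f, base_idx] - cen) @ rot.T).reshape(-1))

    for cls in ("AT", "GC"):
        if not samples_x[cls]:
            continue
        x = np.array(samples_x[cls])
        y = np.array(samples_y[cls])
        design = np.column_stack([x, np.ones(len(x))])
        w, *_ = np.linalg.lstsq(design, y, rcond=None)
        model.base_w[cls] = w
        model.base_templates[cls] = class_templates[cls]
    return model


def reconstruct(
    cg_traj: TrajectoryEnsemble,
    model: BackmapModel,
    sequence: DuplexSequence | None = None,
) -> tuple[AtomisticEnsemble, dict]:
    """Decode a bead trajectory to heavy-atom frames.

    Overlapping backbone-window predictions are blended by uniform
    averaging in the global frame; bases are then placed per bp from the
    blended backbone.  Returns the atom ensemble and a diagnostics dict
    with seam statistics (pre-blend inter-window disagreement, Å RMS) and
    the C1' deviation of the output from the input beads.
    """
    seq = sequence or cg_traj.topology.sequence
    n_bp = len(seq)
    window = model.window
    if n_bp < window:
        raise ValueError("duplex shorter than the model window")
    for b in set(seq.watson):
        if _bp_class(b) not in model.base_w:
            raise ValueError(f"model has no base stage for bp class of {b!r}")
    beads = cg_traj.frames
    layout = _structure_layout(seq)
    atom_names, residue_index, bases, bonds = layout
    n_atoms = len(atom_names)
    n_frames = len(beads)
    out = np.zeros((n_frames, n_atoms, 3))

    n_windows = n_bp if seq.circular else n_bp - window + 1
    bb_per_res = len(BACKBONE_ATOMS)

    counts = np.zeros(n_atoms)
    window_cache = []
    for w0 in range(n_windows):
        bb_idx = _backbone_indices(layout, n_bp, w0, window)
        window_cache.append(bb_idx)
        counts[bb_idx] += 1.0

    seam_sq = np.zeros(n_atoms)
    for f in range(n_frames):
        acc = np.zeros((n_atoms, 3))
        acc_sq = np.zeros(n_atoms)
        for w0, bb_idx in enumerate(window_cache):
            wb = _window_beads(beads[f : f + 1], n_bp, w0, window)[0]
            local, rot, cen = _superpose_onto(wb, model.bead_template)
            pred_local = (model._features(local) @ model.backbone_w).reshape(-1, 3)
            pred = pred_local @ rot + cen
            acc[bb_idx] += pred
            acc_sq[bb_idx] += np.sum(pred * pred, axis=1)
        bb_mask = counts > 0
        acc[bb_mask] /= counts[bb_mask, None]
        mean_sq = np.zeros(n_atoms)
        mean_sq[bb_mask] = acc_sq[bb_mask] / counts[bb_mask]
        seam_sq += np.maximum(
            mean_sq - np.sum(acc * acc, axis=1), 0.0
        )
        out[f] = acc

        # base stage from the blended backbone
        for p in range(n_bp):
            wbase = seq.watson[p]
            cls = _bp_class(wbase)
            res_w, res_c = p, 2 * n_bp - 1 - p
            if wbase in _PURINES:
                first, second = res_w, res_c
                pur_base, pyr_base = wbase, seq.crick[n_bp - 1 - p]
            else:
                first, second = res_c, res_w
                pur_base, pyr_base = seq.crick[n_bp - 1 - p], wbase
            bb_idx = np.concatenate(
                [_res_atoms(layout, first, BACKBONE_ATOMS),
                 _res_atoms(layout, second, BACKBONE_ATOMS)]
            )
            base_idx = np.concatenate(
                [_res_atoms(layout, first, BASE_ATOMS[pur_base]),
                 _res_atoms(layout, second, BASE_ATOMS[pyr_base])]
            )
            local, rot, cen = _superpose_onto(
                out[f, bb_idx], model.base_templates[cls]
            )
            x = np.append(local.reshape(-1), 1.0)
            pred_local = (x @ model.base_w[cls]).reshape(-1, 3)
            out[f, base_idx] = pred_local @ rot + cen

    structure = AtomisticStructure(
        sequence=seq,
        atom_names=atom_names,
        residue_index=residue_index,
        residue_base=bases,
        coords=out[0].copy(),
        bonds=bonds,
        provenance={
            "decoder": "cgdna two-stage window regression",
            "window": window,
            "clash_relaxation": "not applied",
        },
    )
    ens = AtomisticEnsemble(structure=structure, frames=out)

    c1 = np.array(
        [i for i in range(n_atoms) if atom_names[i] == "C1'"], dtype=np.intp
    )
    c1_dev = float(np.max(np.linalg.norm(out[:, c1] - beads, axis=2)))
    bb_sel = counts > 0
    diagnostics = {
        "n_windows": n_windows,
        "seam_rms": float(
            np.sqrt(np.mean(seam_sq[bb_sel] / n_frames))
        ),
        "c1_max_deviation": c1_dev,
    }
    return ens, diagnostics


def _res_atoms(layout, residue: int, names: list[str]) -> np.ndarray:
    atom_names, residue_index, _bases, _bonds = layout
    sel = np.where(residue_index == residue)[0]
    nm = {atom_names[i]: i for i in sel}
    return np.array([nm[a] for a in names], dtype=np.intp)


# ---------------------------------------------------------------------------
# clash relaxation


@dataclass
class StericSettings:
    """Soft-sphere relaxation: push non-bonded atoms beyond ``r_min``.

    ``k`` is the quadratic repulsion constant, ``step`` the steepest
    descent step, ``max_displacement`` the per-atom cap per iteration.
    """

    r_min: float = 1.7  # Å
    k: float = 10.0
    step: float = 0.02
    max_displacement: float = 0.05
    max_iter: int = 200


def relax_clashes(
    structure: AtomisticStructure, settings: StericSettings | None = None
) -> tuple[AtomisticStructure, dict]:
    """Steepest descent on a soft-sphere repulsion E = k (r_min - r)^2 over
    non-bonded pairs; bonded (1-2) pairs from the template connectivity are
    excluded.  Clash-free inputs are returned unchanged; unresolved clashes
    after ``max_iter`` produce a warning and the partially relaxed
    structure.
    """
    settings = settings or StericSettings()
    coords = structure.coords.copy()
    bonded = {(min(a, b), max(a, b)) for a, b in structure.bonds}
    n = len(coords)
    total_disp = np.zeros(n)
    clashes: list[tuple[int, int, float]] = []
    for _ in range(settings.max_iter):
        tree = cKDTree(coords)
        pairs = tree.query_pairs(settings.r_min, output_type="ndarray")
        if len(pairs):
            keys = np.minimum(pairs[:, 0], pairs[:, 1]), np.maximum(
                pairs[:, 0], pairs[:, 1]
            )
            keep = np.array(
                [(a, b) not in bonded for a, b in zip(*keys)], dtype=bool
            )
            pairs = pairs[keep]
        if len(pairs) == 0:
            clashes = []
            break
        i, j = pairs[:, 0], pairs[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-6)
        # force magnitude 2k(r_min - r) along the pair axis
        fmag = 2.0 * settings.k * (settings.r_min - r)
        u = d / r[:, None]
        grad = np.zeros_like(coords)
        contrib = fmag[:, None] * u
        np.add.at(grad, i, contrib)
        np.add.at(grad, j, -contrib)
        move = -settings.step * grad
        norms = np.linalg.norm(move, axis=1)
        over = norms > settings.max_displacement
        move[over] *= (settings.max_displacement / norms[over])[:, None]
        coords += move
        total_disp += np.linalg.norm(move, axis=1)
        clashes = [(int(a), int(b), float(x)) for a, b, x in zip(i, j, r)]
    if clashes:
        logger.warning(
            "clash relaxation left %d unresolved pairs (closest %.2f Å)",
            len(clashes),
            min(c[2] for c in clashes),
        )
    relaxed = AtomisticStructure(
        sequence=structure.sequence,
        atom_names=structure.atom_names,
        residue_index=structure.residue_index,
        residue_base=structure.residue_base,
        coords=coords,
        bonds=structure.bonds,
        provenance={
            **structure.provenance,
            "clash_relaxation": "soft-sphere steepest descent "
            f"(r_min={settings.r_min} Å; geometric clean-up, not a "
            "force-field minimisation)",
        },
    )
    diagnostics = {
        "mean_displacement": float(total_disp.mean()),
        "max_displacement": float(total_disp.max()),
        "unresolved_clashes": clashes,
    }
    return relaxed, diagnostics
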