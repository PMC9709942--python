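"""Structural-ensemble precision: backbone RMSD to the iterative mean.

NMR structure depositions contain several conformers; the standard
precision statistic is the average RMSD of the conformers to their mean
structure after optimal rigid-body superposition.  Because the mean
itself depends on the superposition, the mean and the alignment are
iterated to convergence (Kabsch superposition onto the running mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "StructureEnsemble",
    "read_ensemble",
    "write_ensemble",
    "rmsd_to_mean",
    "BACKBONE_HEAVY",
]

BACKBONE_HEAVY = ("N", "CA", "C", "O")


@dataclass
class StructureEnsemble:
    """Conformer coordinates (n_models, n_atoms, 3 in Angstrom) with labels."""

    coords: np.ndarray
    atom_labels: list  # (residue number, residue name, atom name)
    model_ids: list

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("an ensemble requires >= 2 conformers")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def read_ensemble(
    path,
    residues: tuple[int, int] = (1, 14),
    atoms=BACKBONE_HEAVY,
) -> StructureEnsemble:
    """Read a multi-model PDB/mmCIF file restricted to a residue/atom selection.

    All models must contain the identical atom set within the selection;
    a discrepancy is reported atom by atom.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    lo, hi = residues
    atoms = tuple(atoms)

    per_model = []
    labels_per_model = []
    model_ids = []
    for model in st:
        coords, labels = [], []
        chain = model[0]
        for res in chain:
            seqid = res.seqid.num
            if not (lo <= seqid <= hi):
                continue
            for name in atoms:
                atom = res.find_atom(name, "*")
                if atom is not None:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    labels.append((seqid, res.name, name))
        per_model.append(np.asarray(coords))
        labels_per_model.append(labels)
        model_ids.append(model.num if hasattr(model, "num") else model.name)

    if len(per_model) < 2:
        raise ValueError(f"{path}: ensemble requires >= 2 models, found {len(per_model)}")
    ref = labels_per_model[0]
    for mid, labels in zip(model_ids[1:], labels_per_model[1:]):
        if labels != ref:
            missing = set(map(tuple, ref)) ^ set(map(tuple, labels))
            raise ValueError(
                f"{path}: model {mid} atom set differs from model "
                f"{model_ids[0]} in selection: {sorted(missing)}"
            )
    return StructureEnsemble(np.stack(per_model), ref, model_ids)


def write_ensemble(ens: StructureEnsemble, path, sequence_offset: int = 0) -> None:
    """Write the ensemble as a minimal multi-model PDB file."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for i in range(ens.n_models):
        model = gemmi.Model(i + 1)
        chain = gemmi.Chain("A")
        current = None
        res = None
        for (seqid, resname, aname), xyz in zip(ens.atom_labels, ens.coords[i]):
            if seqid != current:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(seqid + sequence_offset, " ")
                chain.add_residue(res)
                res = chain[-1]
                current = seqid
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(aname[0])
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal least-squares superposition of centered mobile onto centered target."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return mobile @ rot.T


def rmsd_to_mean(
    ens: StructureEnsemble,
    tol: float = 1e-6,
    max_iter: int = 100,
    return_per_model: bool = False,
):
    """Average RMSD of conformers to their converged superposed mean.

    Each conformer is centered and Kabsch-superimposed onto the current
    mean structure; the mean is recomputed and the cycle repeated until
    it moves by less than ``tol`` (Angstrom RMS).  The returned statistic
    is the mean over conformers of the RMSD to the final mean.
    """
    x = ens.coords - ens.coords.mean(axis=1, keepdims=True)
    mean = x[0].copy()
    mean -= mean.mean(axis=0)
    for _ in range(max_iter):
        aligned = np.stack([_kabsch(xi, mean) for xi in x])
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        shift = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        x = aligned
        if shift < tol:
            break
    else:
        raise RuntimeError(f"mean structure did not converge in {max_iter} iterations")
    per_model = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=1))
    avg = float(per_model.mean())
    if return_per_model:
        return avg, per_model
    return avg
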