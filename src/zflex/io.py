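"""Readers and writers for the formats the pipeline touches.

Volumes and particle stacks are MRC2014 (mode 2, voxel size in the
header); particle metadata is STAR in the RELION dialect; atomic models
are PDB.  All three go through gemmi.  Coefficient sets use a small
versioned text format so they can be inspected and diffed:

    zflex-coeffs v1
    <N> <L> <p> <scale_radius_A>
    <l> <n> <m> <ax> <ay> <az>      # one row per index, enumeration order
"""

from __future__ import annotations

import logging

import numpy as np
import gemmi

from .basis import BasisSpec, enumerate_indices
from .field import AtomicModel, CoefficientSet, VolumeGrid
from .imaging import CTFParams, ParticleImage, Pose

log = logging.getLogger("zflex")

__all__ = [
    "read_volume", "write_volume",
    "read_particles", "write_particles",
    "read_model", "write_model",
    "read_coefficients", "write_coefficients",
]


# ---------------------------------------------------------------------------
# MRC volumes

def write_volume(path, v: VolumeGrid) -> None:
    """Write a cubic volume as MRC2014 mode 2 with voxel size in the header."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(v.values, dtype=np.float32))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    a = v.box * v.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(a, a, a, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> VolumeGrid:
    """Read an MRC2014 map; errors on non-cubic input."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True, dtype=float)
    if arr.ndim != 3 or len(set(arr.shape)) != 1:
        raise ValueError(
            f"{path}: expected a cubic volume, got grid dimensions {arr.shape}"
        )
    sp = m.grid.spacing
    if not np.allclose(sp, sp[0], rtol=1e-4):
        raise ValueError(f"{path}: anisotropic voxel size {sp} not supported")
    return VolumeGrid(arr, float(sp[0]))


# ---------------------------------------------------------------------------
# particle stacks + STAR metadata

_ANGLE_COLS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
_SHIFT_COLS = ("_rlnOriginXAngst", "_rlnOriginYAngst")
_CTF_COLS = ("_rlnDefocusU", "_rlnDefocusV", "_rlnDefocusAngle",
             "_rlnVoltage", "_rlnSphericalAberration",
             "_rlnAmplitudeContrast")


def write_particles(star_path, stack_path, particles: list) -> None:
    """Write particles as an MRC stack plus a RELION-dialect STAR table."""
    if not particles:
        raise ValueError("no particles to write")
    box = particles[0].box
    px = particles[0].pixel_size
    stack = np.stack([p.pixels for p in particles]).astype(np.float32)
    grid = gemmi.FloatGrid(np.ascontiguousarray(stack))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    grid.set_unit_cell(gemmi.UnitCell(len(particles) * px, box * px,
                                      box * px, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(stack_path))

    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    tags = ["_rlnImageName", "_rlnImagePixelSize", *_ANGLE_COLS,
            *_SHIFT_COLS, *_CTF_COLS]
    loop = block.init_loop("", tags)
    import os

    stack_name = os.path.basename(str(stack_path))
    for i, p in enumerate(particles):
        ctf = p.ctf or CTFParams()
        loop.add_row([
            f"{i + 1:06d}@{stack_name}",
            f"{px:.17g}",
            f"{p.pose.rot:.17g}", f"{p.pose.tilt:.17g}", f"{p.pose.psi:.17g}",
            f"{p.pose.sx:.17g}", f"{p.pose.sy:.17g}",
            f"{ctf.defocus_u:.17g}", f"{ctf.defocus_v:.17g}",
            f"{ctf.defocus_angle:.17g}", f"{ctf.voltage:.17g}",
            f"{ctf.cs:.17g}", f"{ctf.amplitude_contrast:.17g}",
        ])
    doc.write_file(str(star_path))


def _find_block(doc):
    for b in doc:
        if b.find_loop("_rlnAngleRot"):
            return b
    raise ValueError("no STAR block with particle angles found")


def read_particles(star_path, stack_path=None) -> list:
    """Read particles from STAR metadata plus their MRC stack.

    ``stack_path`` overrides the stack file named in rlnImageName.
    Missing shift columns default to 0 (with a warning); missing CTF
    columns yield particles without CTF.
    """
    import os

    doc = gemmi.cif.read_file(str(star_path))
    block = _find_block(doc)

    def col(tag):
        vals = list(block.find_loop(tag))
        return vals or None

    names = col("_rlnImageName")
    if names is None:
        raise ValueError("missing mandatory STAR column _rlnImageName")
    angles = []
    for tag in _ANGLE_COLS:
        v = col(tag)
        if v is None:
            raise ValueError(f"missing mandatory STAR column {tag}")
        angles.append([float(x) for x in v])
    shifts = []
    for tag in _SHIFT_COLS:
        v = col(tag)
        if v is None:
            log.warning("STAR column %s missing; shifts default to 0", tag)
            v = ["0"] * len(names)
        shifts.append([float(x) for x in v])
    ctf_cols = [col(t) for t in _CTF_COLS]
    have_ctf = all(v is not None for v in ctf_cols)
    px_col = col("_rlnImagePixelSize")

    if stack_path is None:
        stack_name = names[0].split("@", 1)[1]
        stack_path = os.path.join(os.path.dirname(str(star_path)), stack_name)
    m = gemmi.read_ccp4_map(str(stack_path))
    stack = np.array(m.grid, copy=True, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"{stack_path}: expected an image stack")

    out = []
    for i, name in enumerate(names):
        idx = int(name.split("@", 1)[0]) - 1
        tilt = angles[1][i]
        if not (0.0 <= tilt <= 180.0):
            raise ValueError(
                f"particle {i}: tilt {tilt} outside [0, 180] degrees"
            )
        pose = Pose(rot=angles[0][i], tilt=tilt, psi=angles[2][i],
                    sx=shifts[0][i], sy=shifts[1][i])
        ctf = None
        if have_ctf:
            ctf = CTFParams(
                defocus_u=float(ctf_cols[0][i]),
                defocus_v=float(ctf_cols[1][i]),
                defocus_angle=float(ctf_cols[2][i]),
                voltage=float(ctf_cols[3][i]),
                cs=float(ctf_cols[4][i]),
                amplitude_contrast=float(ctf_cols[5][i]),
            )
        px = float(px_col[i]) if px_col else float(m.grid.spacing[1])
        out.append(ParticleImage(pixels=stack[idx], pixel_size=px,
                                 pose=pose, ctf=ctf, id=name))
    return out


# ---------------------------------------------------------------------------
# atomic models (PDB)

def write_model(path, mdl: AtomicModel) -> None:
    st = gemmi.Structure()
    st.name = "zflex"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for el, ch, resid, pos in zip(mdl.elements, mdl.chains, mdl.residue_ids,
                                  mdl.positions):
        if ch not in chains:
            chains[ch] = gemmi.Chain(ch)
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(int(resid), " ")
        atom = gemmi.Atom()
        atom.name = str(el)
        atom.element = gemmi.Element(str(el))
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        chains[ch].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_model(path) -> AtomicModel:
    st = gemmi.read_structure(str(path))
    elements, chains, resids, positions = [], [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    chains.append(chain.name)
                    resids.append(res.seqid.num)
                    positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    return AtomicModel(elements, chains, resids, np.array(positions))


# ---------------------------------------------------------------------------
# coefficient tables

def write_coefficients(path, c: CoefficientSet) -> None:
    with open(path, "w") as fh:
        fh.write("zflex-coeffs v1\n")
        fh.write(f"{c.spec.N} {c.spec.L} {c.spec.p:.10g} "
                 f"{c.scale_radius:.10g}\n")
        for (l, n, m), row in zip(enumerate_indices(c.spec), c.alphas):
            fh.write(f"{l} {n} {m} {row[0]:.17g} {row[1]:.17g} "
                     f"{row[2]:.17g}\n")


def read_coefficients(path) -> CoefficientSet:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != "zflex-coeffs v1":
            raise ValueError(f"{path}: not a zflex coefficient table")
        N, L, p, radius = fh.readline().split()
        spec = BasisSpec(int(N), int(L), float(p))
        indices = enumerate_indices(spec)
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) != len(indices):
        raise ValueError(
            f"{path}: expected {len(indices)} coefficient rows, got {len(rows)}"
        )
    alphas = np.empty((len(indices), 3))
    for i, (row, idx) in enumerate(zip(rows, indices)):
        if tuple(int(x) for x in row[:3]) != tuple(idx):
            raise ValueError(f"{path}: row {i} index mismatch")
        alphas[i] = [float(x) for x in row[3:6]]
    return CoefficientSet(spec, alphas, float(radius))
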