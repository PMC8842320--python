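"""File formats: extended XYZ (with charge/layer columns), LAMMPS data
files for cross-checking against external MD codes, and CSV friction traces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import (SystemConfiguration, Supercell, MoleculeTemplate,
                       SPECIES)

_RIGID_NAMES = {0: "SUB", 1: "SUP"}
_LAYER_TAGS = {(0, False): "SUB-molecule", (1, False): "SUP-molecule",
               (0, True): "SUB-rigid", (1, True): "SUP-rigid"}


def species_names(config: SystemConfiguration):
    out = []
    for sp, lay in zip(config.species, config.layer):
        out.append(SPECIES[sp] if sp >= 0 else _RIGID_NAMES[int(lay)])
    return out


def write_extxyz(path, config: SystemConfiguration, positions=None,
                 comment_extra=""):
    """Extended-XYZ frame: species, position, charge and layer tag columns."""
    pos = config.positions if positions is None else positions
    names = species_names(config)
    box = config.box
    lz = max(box.z_extent + 2.0, 1.0)
    with open(path, "w") as fh:
        fh.write(f"{config.n_particles}\n")
        fh.write(
            f'Lattice="{box.l_x} 0.0 0.0 0.0 {box.l_y} 0.0 0.0 0.0 {lz}" '
            'Properties=species:S:1:pos:R:3:charge:R:1:layer:S:1 '
            f'pbc="T T F" {comment_extra}'.rstrip() + "\n")
        for i in range(config.n_particles):
            tag = _LAYER_TAGS[(int(config.layer[i]),
                               bool(config.species[i] < 0))]
            fh.write(f"{names[i]:4s} {pos[i, 0]:.9f} {pos[i, 1]:.9f} "
                     f"{pos[i, 2]:.9f} {config.charges[i]:.6f} {tag}\n")


def read_extxyz(path):
    """Read back a frame written by :func:`write_extxyz`.

    Returns a dict with positions, species names, charges, layer tags and
    the box (Supercell).
    """
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline()
        lat = header.split('Lattice="')[1].split('"')[0].split()
        l_x, l_y = float(lat[0]), float(lat[4])
        names, ppos, charges, tags = [], [], [], []
        for _ in range(n):
            parts = fh.readline().split()
            names.append(parts[0])
            ppos.append([float(p) for p in parts[1:4]])
            charges.append(float(parts[4]))
            tags.append(parts[5])
    return {"positions": np.array(ppos), "species": names,
            "charges": np.array(charges), "layer_tags": tags,
            "box": Supercell(l_x, l_y)}


def write_lammps_data(path, config: SystemConfiguration,
                      ff_params=None, positions=None):
    """LAMMPS data file (atom_style full): atoms, bonds, angles, masses.

    Atom types 1..7 are the molecule species CA..NP2, 8/9 the SUB/SUP rigid
    beads; two bond types (r_eq 0.16 / 0.67 nm) and two angle types
    (180 / 111 deg).  Lengths stay in nm, charges in e.
    """
    pos = config.positions if positions is None else positions
    box = config.box
    tmpl = config.template
    atype = np.where(config.species >= 0, config.species + 1,
                     np.where(config.layer == 0, 8, 9))
    btype = np.where(np.array([tmpl.bond_r_eq[s]
                               for s in config.bond_slot]) > 0.5, 2, 1)
    gtype = np.where(np.array([tmpl.angle_theta_eq_deg[s]
                               for s in config.angle_slot]) < 150.0, 2, 1)
    masses = {t + 1: tmpl.masses_amu[t] for t in range(7)}
    masses[8] = masses[9] = 50.0
    zlo = float(pos[:, 2].min()) - 2.0
    zhi = float(pos[:, 2].max()) + 2.0
    with open(path, "w") as fh:
        fh.write("LAMMPS data file: zwitterionic bilayer contact "
                 "(units: nm, eV, e)\n\n")
        fh.write(f"{config.n_particles} atoms\n")
        fh.write(f"{len(config.bonds)} bonds\n")
        fh.write(f"{len(config.angles)} angles\n\n")
        fh.write("9 atom types\n2 bond types\n2 angle types\n\n")
        fh.write(f"0.0 {box.l_x} xlo xhi\n0.0 {box.l_y} ylo yhi\n")
        fh.write(f"{zlo} {zhi} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for t in range(1, 10):
            fh.write(f"{t} {masses[t]}\n")
        fh.write("\nAtoms # full\n\n")
        for i in range(config.n_particles):
            mol = int(config.molecule_id[i]) + 1  # 0 = rigid beads
            fh.write(f"{i + 1} {mol} {atype[i]} {config.charges[i]:.6f} "
                     f"{pos[i, 0]:.9f} {pos[i, 1]:.9f} {pos[i, 2]:.9f}\n")
        fh.write("\nBonds\n\n")
        for b, (i, j) in enumerate(config.bonds):
            fh.write(f"{b + 1} {btype[b]} {i + 1} {j + 1}\n")
        fh.write("\nAngles\n\n")
        for a, (i, j, k) in enumerate(config.angles):
            fh.write(f"{a + 1} {gtype[a]} {i + 1} {j + 1} {k + 1}\n")


def write_trace_csv(path, trace: pd.DataFrame):
    """Friction trace CSV with a units header line."""
    with open(path, "w") as fh:
        fh.write("# zwitterslide friction trace; units: time_ps=ps, "
                 "x_stage=nm, x_sup=nm, shear_mpa=MPa, hooking_pct=%, "
                 "U_ev=eV, d_nm=nm, T_inst_K=K\n")
        for key in ("area_nm2", "k_spring", "v_stage_m_s", "load_mpa",
                    "temperature_K"):
            if key in trace.attrs:
                fh.write(f"# {key} = {trace.attrs[key]}\n")
        trace.to_csv(fh, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    attrs = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                try:
                    attrs[key.strip()] = float(val)
                except ValueError:
                    pass   # prose header line, not a key = value pair
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    df.attrs.update(attrs)
    return df
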