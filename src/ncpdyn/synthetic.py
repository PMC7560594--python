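"""Synthetic nucleosomal-DNA sections with known ground truth.

This module emulates the *statistical* structure of microsecond MD ensembles
of abasic-site-bearing DNA — two-state intra/extrahelical flipping with
controllable occupancy, coupled lesion/orphan-base ejection ("inchworm"
versus B-like regimes), scripted histone-tail contact episodes, designed
section bends, and Gaussian coordinate noise — without any force field.
It is a geometry/kinetics emulator, not an MD engine: bonded continuity
between successive backbone units, solvent, and energetics are out of scope.

Every stochastic output is a pure function of the seed.  The generator
returns ground-truth per-frame state labels alongside coordinates so that
threshold-based classifiers downstream can be tested against a known truth.

Pair-geometry calibration
-------------------------
Nucleotide geometry comes from idealized chemical-component templates
(biotite's bundled CCD).  The Watson–Crick pair placement is parameterised by
the C1'–C1' distance and the in-plane glycosidic angle λ, calibrated so that
the mass-weighted nucleobase-COM distance across a built dA:dT pair equals
the 6.8 Å canonical B-DNA reference used by the ejection descriptor
(defaults C1'–C1' = 10.8 Å, λ = 62°).  Ideal Watson–Crick hydrogen-bond
geometry would give a ~5.8 Å base-COM distance; honouring the 6.8 Å
convention therefore opens the pair slightly (N1···N3 ≈ 3.6 Å).  This is an
explicit emulator convention — none of the analyses depend on hydrogen-bond
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure.info import residue as _ccd_residue

from .structure import (
    PHOSPHATE_ATOMS,
    SUGAR_ATOMS,
    SiteSpec,
    StrandRange,
    Structure,
    Trajectory,
    canonical_lesion_name,
    mass_of,
    select_atoms,
)

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RES_NAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

# Calibrated pair-frame constants (see module docstring).
C1_C1_DISTANCE = 10.8      # Å across a Watson–Crick pair
GLYCOSIDIC_LAMBDA = 62.0   # degrees, in-plane angle of the C1'->N bond

DEFAULT_FLIP_ANGLE = 110.0  # degrees about the flanking P–P axis


@dataclass
class SynthConfig:
    """World description for the synthetic duplex generator.

    ``sequence`` is the 5'->3' sequence of strand A (chain "A"); chain "B"
    carries the Watson–Crick complement, numbered 1..n in its own 5'->3'
    direction so that A:i pairs B:(n+1-i).  Rise/twist defaults follow the
    fiber-model convention (3.38 Å / 36°).
    """

    sequence: str
    lesion_position: int | None = None
    lesion_type: str = "AP"
    orphan_position: int | None = None
    helical_rise: float = 3.38
    helical_twist: float = 36.0
    noise_sigma: float = 0.0
    seed: int = 0
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.lesion_type not in ("AP", "THF"):
            raise ValueError("lesion_type must be 'AP' or 'THF'")


@dataclass
class FlipSpec:
    """Two-state flipping kinetics for one site.

    markov mode: first-order chain with per-frame probabilities ``p_out``
    (intra->extra) and ``p_in`` (extra->intra); the stationary extrahelical
    occupancy is p_out/(p_out+p_in).  exact_fraction mode: exactly
    round(fraction*n_frames) frames are extrahelical, evenly spaced (the
    occupancy is a percentage of time, not necessarily consecutive).
    ``couple_to`` names another site whose hidden chain drives this one
    (inchworm coupling) with an independent per-frame emission-flip
    probability ``emission_noise``.
    """

    site: tuple[str, int]
    mode: str = "markov"
    p_out: float = 0.0
    p_in: float = 0.0
    fraction: float | None = None
    couple_to: tuple[str, int] | None = None
    emission_noise: float = 0.0
    flip_angle: float = DEFAULT_FLIP_ANGLE

    def __post_init__(self) -> None:
        if self.mode not in ("markov", "exact_fraction"):
            raise ValueError(f"unknown flip mode {self.mode!r}")
        for p in (self.p_out, self.p_in, self.emission_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mode == "exact_fraction":
            if self.fraction is None:
                raise ValueError("exact_fraction mode requires a fraction")
            if not 0.0 <= self.fraction <= 1.0:
                raise ValueError("fraction must lie in [0, 1]")


@dataclass
class ContactScript:
    """Scripted residence episodes of a charged tail probe.

    ``episodes`` is a list of half-open frame windows ``(start, end,
    target_distance)``; outside every episode the probe sits at
    ``off_distance`` from the site.  Windows must be disjoint and inside
    [0, n_frames).
    """

    episodes: list[tuple[int, int, float]]
    off_distance: float = 20.0
    probe_kind: str = "LYS_NZ"   # or "NTERM_N"
    chain_id: str = "P"
    residue_number: int = 1

    def validate(self, n_frames: int) -> None:
        last_end = 0
        for start, end, target in sorted(self.episodes):
            if start < 0 or end > n_frames or end <= start:
                raise ValueError(
                    f"episode ({start}, {end}) outside [0, {n_frames})"
                )
            if start < last_end:
                raise ValueError("episodes must be non-overlapping")
            if target >= self.off_distance:
                raise ValueError(
                    f"target_distance {target} must be < off_distance "
                    f"{self.off_distance}"
                )
            last_end = end


# ---------------------------------------------------------------------------
# Nucleotide templates and pair placement
# ---------------------------------------------------------------------------

def _heavy_template(res_name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(names, elements, coords) of the heavy atoms of a CCD nucleotide."""
    r = _ccd_residue(res_name)
    keep = (r.element != "H") & (r.atom_name != "OP3")
    names = np.array([a for a in r.atom_name[keep]], dtype=object)
    elements = np.array([e for e in r.element[keep]], dtype=object)
    return names, elements, np.asarray(r.coord[keep], dtype=float)


def _glycosidic_nitrogen(base: str) -> str:
    return "N9" if base in ("A", "G") else "N1"


def _ring_triplet(base: str) -> tuple[str, str, str]:
    return ("N9", "C4", "C8") if base in ("A", "G") else ("N1", "C2", "C6")


def _place_nucleotide(base: str, strand: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place one nucleotide template into the common pair frame.

    Pair frame: pair plane z=0, C1' atoms at (±D/2, 0, 0), glycosidic bonds
    at angle λ from the C1'–C1' axis.  Strand B is the strand-A placement
    rotated 180° about the in-plane y axis (the pair pseudo-dyad), which
    yields the antiparallel Watson–Crick arrangement.
    """
    names, elements, X = _heavy_template(_RES_NAME[base])
    idx = {n: i for i, n in enumerate(names)}
    c1 = X[idx["C1'"]]
    ng = X[idx[_glycosidic_nitrogen(base)]]
    a, b, c = (X[idx[k]] for k in _ring_triplet(base))
    normal = np.cross(b - a, c - a)
    normal /= np.linalg.norm(normal)
    u = ng - c1
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    w /= np.linalg.norm(w)
    src = np.stack([u, w, np.cross(u, w)], axis=1)

    lam = np.radians(GLYCOSIDIC_LAMBDA)
    ut = np.array([np.cos(lam), np.sin(lam), 0.0])
    nt = np.array([0.0, 0.0, 1.0])
    wt = np.cross(nt, ut)
    tgt = np.stack([ut, wt, np.cross(ut, wt)], axis=1)
    rot = tgt @ src.T
    placed = (X - c1) @ rot.T + np.array([-C1_C1_DISTANCE / 2, 0.0, 0.0])
    if strand == "B":
        flip = np.diag([-1.0, 1.0, -1.0])  # 180° about y
        placed = placed @ flip.T
    return names, elements, placed


def _rotation_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_bdna(config: SynthConfig) -> Structure:
    """Deterministic canonical B-DNA duplex for ``config.sequence``.

    Successive base pairs are related by ``helical_rise`` along z and
    ``helical_twist`` about it.  Chain "A" holds the given sequence
    (residues 1..n, 5'->3'); chain "B" the complement (residues 1..n in its
    own 5'->3' order, pairing A:i with B:(n+1-i)).  Heavy atoms only.
    """
    seq = config.sequence
    n = len(seq)
    rows_a, rows_b = [], []
    for k, base in enumerate(seq):
        rot = _rotation_z(k * config.helical_twist)
        shift = np.array([0.0, 0.0, k * config.helical_rise])
        for strand, b in (("A", base), ("B", COMPLEMENT[base])):
            names, elements, placed = _place_nucleotide(b, strand)
            coords = placed @ rot.T + shift
            res_id = k + 1 if strand == "A" else n - k
            rec = (strand, res_id, _RES_NAME[b], names, elements, coords)
            (rows_a if strand == "A" else rows_b).append(rec)
    rows_b.sort(key=lambda r: r[1])

    name_l, elem_l, res_l, chain_l, rid_l, coord_l = [], [], [], [], [], []
    for strand_rows in (rows_a, rows_b):
        for chain, rid, rname, names, elements, coords in strand_rows:
            for j in range(len(names)):
                chain_l.append(chain)
                rid_l.append(rid)
                res_l.append(rname)
                name_l.append(names[j])
                elem_l.append(elements[j])
                coord_l.append(coords[j])
    n_atoms = len(name_l)
    masses = np.array([mass_of(e) for e in elem_l])
    return Structure(
        np.arange(1, n_atoms + 1),
        np.array(name_l, dtype=object),
        np.array(res_l, dtype=object),
        np.array(chain_l, dtype=object),
        np.array(rid_l, dtype=int),
        np.array(elem_l, dtype=object),
        masses,
        np.array(coord_l, dtype=float),
    )


def alternating_tetramer_sequence(n_bp: int, start_with: str = "GC") -> str:
    """A sequence alternating dG-dC and dA-dT tetramers (study-style motif)."""
    blocks = {"GC": "GCGC", "AT": "ATAT"}
    if start_with not in blocks:
        raise ValueError("start_with must be 'GC' or 'AT'")
    order = ["GC", "AT"] if start_with == "GC" else ["AT", "GC"]
    out = []
    i = 0
    while len(out) < n_bp:
        out.extend(blocks[order[i % 2]])
        i += 1
    return "".join(out[:n_bp])


# ---------------------------------------------------------------------------
# Lesion surgery
# ---------------------------------------------------------------------------

def apply_lesion(structure: Structure, position: tuple[str, int],
                 lesion_type: str) -> Structure:
    """Replace the base at ``position`` by an abasic site.

    All nucleobase heavy atoms are removed; sugar and phosphate atoms are
    retained and the residue is renamed.  For a deoxyribo-type AP site an
    O1' hydroxyl pseudo-atom is placed along the former glycosidic
    (C1'->N) vector; the THF analog lacks that oxygen function.
    """
    if lesion_type not in ("AP", "THF"):
        raise ValueError("lesion_type must be 'AP' or 'THF'")
    chain, resnum = position
    res_idx = structure.residue_atom_indices(chain, resnum)
    if res_idx.size == 0:
        raise ValueError(f"no residue {resnum} on chain {chain}")
    res_name = str(structure.res_name[res_idx[0]])
    if canonical_lesion_name(res_name) is not None:
        raise ValueError(
            f"residue {chain}:{resnum} ({res_name}) is already abasic"
        )

    names = structure.name[res_idx]
    glyc = "N9" if any(n == "N9" for n in names) else "N1"
    c1_idx = res_idx[[i for i, n in enumerate(names) if n == "C1'"]]
    n_idx = res_idx[[i for i, n in enumerate(names) if n == glyc]]
    if c1_idx.size != 1 or n_idx.size != 1:
        raise ValueError(
            f"residue {chain}:{resnum} lacks C1'/{glyc} atoms for lesion "
            "placement"
        )
    c1 = structure.coords[c1_idx[0]]
    u = structure.coords[n_idx[0]] - c1
    u /= np.linalg.norm(u)

    base_mask = np.array([
        structure.name[i] not in SUGAR_ATOMS
        and structure.name[i] not in PHOSPHATE_ATOMS
        for i in res_idx
    ])
    drop = set(res_idx[base_mask].tolist())
    keep = np.array([i for i in range(structure.n_atoms) if i not in drop])
    out = structure.subset(keep)

    new_res_idx = out.residue_atom_indices(chain, resnum)
    out.res_name[new_res_idx] = lesion_type

    if lesion_type == "AP":
        # hemiacetal hydroxyl at the base-attachment vector (C-O 1.43 Å)
        insert_at = int(new_res_idx[-1]) + 1
        o1_coord = c1 + 1.43 * u

        def _ins(arr, value):
            return np.concatenate([arr[:insert_at],
                                   np.array([value], dtype=arr.dtype),
                                   arr[insert_at:]])

        out = Structure(
            _ins(out.serial, int(out.serial.max()) + 1),
            _ins(out.name, "O1'"),
            _ins(out.res_name, "AP"),
            _ins(out.chain_id, chain),
            _ins(out.res_id, resnum),
            _ins(out.element, "O"),
            _ins(out.mass, mass_of("O")),
            np.concatenate([out.coords[:insert_at], o1_coord[None, :],
                            out.coords[insert_at:]]),
            _ins(out.occupancy, 1.0),
            _ins(out.bfactor, 0.0),
        )
    return out


# ---------------------------------------------------------------------------
# Designed bends
# ---------------------------------------------------------------------------

def bend_arc(structure: Structure, angle: float, *,
             rise: float = 3.38, cap_bp: int = 4) -> Structure:
    """Bend a built duplex so its end tangents differ by ``angle`` degrees.

    The helix axis (z of the builder frame) is remapped onto a planar curve:
    straight caps of ``cap_bp`` base pairs at each end joined by a circular
    arc carrying the full tangent change.  Each base pair is transported
    rigidly (both strands' residues of a pair share one transform), so
    within-pair geometry is exactly preserved and end-segment axis fits
    recover the designed angle.
    """
    if not 0.0 <= angle < 180.0:
        raise ValueError("bend angle must lie in [0, 180)")
    if angle == 0.0:
        return structure.copy()

    chains = structure.chains
    if set(chains) < {"A", "B"}:
        raise ValueError("bend_arc expects a builder duplex with chains A/B")
    n = len(chains["A"])
    if n < 2 * cap_bp + 1:
        raise ValueError(
            f"duplex too short to bend with {cap_bp}-bp straight caps"
        )
    theta = np.radians(angle)
    s_a = (cap_bp - 0.5) * rise
    s_b = ((n - 1) - (cap_bp - 0.5)) * rise
    kappa = theta / (s_b - s_a)
    radius = 1.0 / kappa

    def axis_frame(s: float) -> tuple[np.ndarray, float]:
        if s <= s_a:
            return np.array([0.0, 0.0, s]), 0.0
        if s <= s_b:
            psi = kappa * (s - s_a)
            pt = np.array([radius * (1 - np.cos(psi)), 0.0,
                           s_a + radius * np.sin(psi)])
            return pt, psi
        end_pt, _ = axis_frame(s_b)
        tangent = np.array([np.sin(theta), 0.0, np.cos(theta)])
        return end_pt + (s - s_b) * tangent, theta

    out = structure.copy()
    res_ids = structure.res_id
    chain_ids = structure.chain_id
    pair_index = np.where(chain_ids == "A", res_ids - 1, n - res_ids)
    for k in range(n):
        sel = np.flatnonzero(pair_index == k)
        z_k = k * rise
        pt, phi = axis_frame(z_k)
        c, s = np.cos(phi), np.sin(phi)
        rot_y = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        local = structure.coords[sel] - np.array([0.0, 0.0, z_k])
        out.coords[sel] = local @ rot_y.T + pt
    return out


# ---------------------------------------------------------------------------
# Flip dynamics
# ---------------------------------------------------------------------------

def _rotate_about_axis(coords: np.ndarray, point: np.ndarray,
                       axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    x = coords - point
    return (
        x * c
        + np.cross(axis, x) * s
        + axis * (x @ axis)[:, None] * (1 - c)
    ) + point


def extrahelical_template(structure: Structure, site: tuple[str, int],
                          angle: float = DEFAULT_FLIP_ANGLE) -> np.ndarray:
    """Coordinates of ``site``'s atoms swung out of the helix.

    The residue is rotated about the axis through its own P atom and the
    next residue's P atom on the same strand; of the two rotation senses the
    one carrying the residue's geometric centre farther from the duplex
    centroid (i.e. into the solvent-facing groove) is chosen.
    """
    chain, resnum = site
    res_idx = structure.residue_atom_indices(chain, resnum)
    if res_idx.size == 0:
        raise ValueError(f"no residue {resnum} on chain {chain}")
    p_self = select_atoms(structure, chain=chain, residue_number=resnum,
                          atom_name="P")
    p_next = select_atoms(structure, chain=chain, residue_number=resnum + 1,
                          atom_name="P")
    if p_self.size != 1 or p_next.size != 1:
        raise ValueError(
            f"residue {chain}:{resnum} needs flanking P atoms (interior "
            "residue) to define the flip axis"
        )
    point = structure.coords[p_self[0]]
    axis = structure.coords[p_next[0]] - point
    centroid = structure.coords.mean(axis=0)
    best, best_d = None, -np.inf
    for sign in (angle, -angle):
        rotated = _rotate_about_axis(structure.coords[res_idx], point, axis,
                                     sign)
        d = np.linalg.norm(rotated.mean(axis=0) - centroid)
        if d > best_d:
            best, best_d = rotated, d
    return best


def _exact_fraction_states(fraction: float, n_frames: int) -> np.ndarray:
    m = int(round(fraction * n_frames))
    states = np.zeros(n_frames, dtype=bool)
    if m > 0:
        idx = ((np.arange(m) + 0.5) * n_frames / m).astype(int)
        states[np.clip(idx, 0, n_frames - 1)] = True
        # guard against collisions from the rounding (only possible at m ~ n)
        short = m - int(states.sum())
        if short:
            free = np.flatnonzero(~states)
            states[free[:short]] = True
    return states


def simulate_states(flips: list[FlipSpec], n_frames: int,
                    seed: int) -> dict[tuple[str, int], np.ndarray]:
    """Ground-truth boolean extrahelical state per site and frame."""
    rng = np.random.default_rng(seed)
    by_site = {f.site: f for f in flips}
    states: dict[tuple[str, int], np.ndarray] = {}

    def resolve(spec: FlipSpec) -> np.ndarray:
        if spec.site in states:
            return states[spec.site]
        if spec.couple_to is not None:
            if spec.couple_to not in by_site:
                raise ValueError(
                    f"coupling references unknown site {spec.couple_to}"
                )
            hidden = resolve(by_site[spec.couple_to])
            flipped = rng.random(n_frames) < spec.emission_noise
            out = hidden ^ flipped
        elif spec.mode == "exact_fraction":
            out = _exact_fraction_states(spec.fraction, n_frames)
        else:
            u = rng.random(n_frames)
            out = np.empty(n_frames, dtype=bool)
            state = False  # start intrahelical
            for t in range(n_frames):
                p = spec.p_in if state else spec.p_out
                if u[t] < p:
                    state = not state
                out[t] = state
        states[spec.site] = out
        return out

    for spec in flips:
        resolve(spec)
    return states


def simulate_flip_dynamics(
    structure: Structure,
    flips: list[FlipSpec],
    n_frames: int,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Generate a flip trajectory plus its ground-truth state table.

    Returns ``(trajectory, labels)`` where ``labels`` has one row per
    (frame, site) with ``state`` in {"intra", "extra"}.  Coordinates are the
    built (intrahelical) structure with flipped residues substituted by
    their extrahelical template, plus i.i.d. Gaussian noise of
    ``noise_sigma`` Å per coordinate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    states = simulate_states(flips, n_frames, seed)
    templates = {
        f.site: extrahelical_template(structure, f.site, f.flip_angle)
        for f in flips
    }
    frames = np.broadcast_to(
        structure.coords, (n_frames, structure.n_atoms, 3)
    ).copy()
    for site, st in states.items():
        res_idx = structure.residue_atom_indices(*site)
        frames[np.ix_(np.flatnonzero(st), res_idx)] = templates[site]
    if noise_sigma > 0:
        noise_rng = np.random.default_rng(seed + 1)
        frames += noise_rng.normal(0.0, noise_sigma, frames.shape)

    rows = []
    for site in states:
        for t in range(n_frames):
            rows.append((t, f"{site[0]}:{site[1]}",
                         "extra" if states[site][t] else "intra"))
    labels = pd.DataFrame(rows, columns=["frame", "site", "state"])
    return Trajectory(structure, frames), labels


# ---------------------------------------------------------------------------
# Scripted tail probe
# ---------------------------------------------------------------------------

_PROBE_ATOMS = {
    # name, element, offset (Å) beyond the contact atom along the retreat axis
    "LYS_NZ": [("NZ", "N", 0.0), ("CA", "C", 2.5), ("N", "N", 3.9)],
    "NTERM_N": [("N", "N", 0.0), ("CA", "C", 1.5), ("C", "C", 2.9)],
}


def add_tail_probe(traj: Trajectory, script: ContactScript,
                   site_atoms: np.ndarray) -> Trajectory:
    """Append a charged-probe residue whose site distance follows a script.

    Per frame, the probe's contact atom (Lys NZ or an N-terminal amine N) is
    placed at the scripted distance from the site's outermost heavy atom
    along the outward direction, so the minimum probe–site distance equals
    the scripted value; the remaining probe atoms trail rigidly behind it.
    """
    script.validate(traj.n_frames)
    site_atoms = np.asarray(site_atoms, dtype=int)
    if site_atoms.size == 0:
        raise ValueError("site_atoms must be non-empty")
    spec_atoms = _PROBE_ATOMS[script.probe_kind]
    res_name = "LYS" if script.probe_kind == "LYS_NZ" else "ALA"

    target = np.full(traj.n_frames, script.off_distance)
    for start, end, dist in script.episodes:
        target[start:end] = dist

    topo = traj.topology
    n_old = topo.n_atoms
    n_new = len(spec_atoms)
    new_frames = np.empty((traj.n_frames, n_old + n_new, 3))
    new_frames[:, :n_old] = traj.frames
    for t in range(traj.n_frames):
        site = traj.frames[t, site_atoms]
        centroid = site.mean(axis=0)
        radial = np.linalg.norm(site - centroid, axis=1)
        anchor = site[int(np.argmax(radial))]
        direction = anchor - centroid
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0, 0])
        for j, (_, _, offset) in enumerate(spec_atoms):
            new_frames[t, n_old + j] = anchor + (target[t] + offset) * direction

    def _cat(arr, values, dtype=None):
        add = np.array(values, dtype=arr.dtype if dtype is None else dtype)
        return np.concatenate([arr, add])

    new_topo = Structure(
        _cat(topo.serial, [int(topo.serial.max()) + 1 + j for j in range(n_new)]),
        _cat(topo.name, [a[0] for a in spec_atoms]),
        _cat(topo.res_name, [res_name] * n_new),
        _cat(topo.chain_id, [script.chain_id] * n_new),
        _cat(topo.res_id, [script.residue_number] * n_new),
        _cat(topo.element, [a[1] for a in spec_atoms]),
        _cat(topo.mass, [mass_of(a[1]) for a in spec_atoms]),
        np.concatenate([topo.coords, new_frames[0, n_old:]]),
        _cat(topo.occupancy, [1.0] * n_new),
        _cat(topo.bfactor, [0.0] * n_new),
    )
    return Trajectory(new_topo, new_frames, traj.frame_stride_ps)


# ---------------------------------------------------------------------------
# Site bookkeeping
# ---------------------------------------------------------------------------

def duplex_site_spec(config: SynthConfig, *, label: str = "site",
                     replicate: str = "MD1") -> SiteSpec:
    """SiteSpec for a generated duplex: full-length section, standard pairing."""
    n = len(config.sequence)
    lesion = ("A", config.lesion_position) if config.lesion_position else ("A", (n + 1) // 2)
    facing = ("B", n + 1 - lesion[1])
    orphan = None
    partner = None
    if config.orphan_position is not None:
        orphan = ("B", config.orphan_position)
        partner = ("A", n + 1 - config.orphan_position)
    return SiteSpec(
        lesion=lesion, facing=facing,
        section=(StrandRange("A", 1, n), StrandRange("B", 1, n)),
        orphan=orphan, orphan_partner=partner,
        label=label, replicate=replicate,
    )


def write_ground_truth(labels: pd.DataFrame, path: str | Path) -> None:
    """Sidecar CSV (frame, site, state) for a generated trajectory."""
    labels.to_csv(path, index=False)
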