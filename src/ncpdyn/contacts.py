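"""Residence frequencies of charged histone-tail groups near damaged sites.

A DNA–protein cross-link at an abasic site requires a nucleophilic amine to
reach the lesion's reactive aldehyde; the geometric precursor tracked here
is the fraction of frames in which any atom of a positively charged group
(lysine NZ, arginine guanidinium, or an N-terminal amine) lies strictly
within a cutoff radius (default 6 Å) of any heavy atom of the damaged-site
residue (backbone and phosphate included — the inclusive reading; the atom
set is configurable through ``site_atoms``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import PercentSummary, aggregate_replicates
from .structure import SelectionError, Structure, Trajectory, select_atoms

# Standard amino-acid residue names (for protein-chain detection).
AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "LYN", "ASH", "GLH", "CYX",
})

_GROUP_ATOMS = {
    "LYS_NZ": ("NZ",),
    "ARG_GUANIDINIUM": ("NE", "NH1", "NH2"),
    "NTERM_N": ("N",),
}


@dataclass(frozen=True)
class ChargedGroup:
    chain: str
    residue_number: int
    residue_name: str
    group_kind: str
    atom_indices: tuple[int, ...]

    @property
    def label(self) -> str:
        one = {"LYS": "K", "ARG": "R"}.get(self.residue_name,
                                           self.residue_name)
        if self.group_kind == "NTERM_N":
            return f"Nterm-{one}{self.residue_number}({self.chain})"
        return f"{one}{self.residue_number}({self.chain})"


@dataclass
class ContactSummary:
    pair_label: str
    summary: PercentSummary

    @property
    def per_replicate(self) -> dict[str, float]:
        return self.summary.per_replicate

    @property
    def all_mean(self) -> float:
        return self.summary.all_mean


def find_charged_groups(structure: Structure,
                        chains: list[str]) -> list[ChargedGroup]:
    """All Lys NZ, Arg guanidinium, and chain N-terminal amine groups.

    Deterministic order: (chain, residue_number), the N-terminal group of a
    residue preceding its side-chain group.  Chains with no protein residues
    contribute nothing.
    """
    groups: list[ChargedGroup] = []
    for chain in chains:
        residues = [
            r for r in structure.chains.get(chain, [])
            if str(structure.res_name[
                structure.residue_atom_indices(chain, r)[0]]) in AMINO_ACIDS
        ]
        for pos, resnum in enumerate(residues):
            res_idx = structure.residue_atom_indices(chain, resnum)
            res_name = str(structure.res_name[res_idx[0]])
            names = {str(structure.name[i]): int(i) for i in res_idx}
            if pos == 0:
                if "N" not in names:
                    raise SelectionError(
                        f"N-terminal residue {chain}:{resnum} ({res_name}) "
                        "has no backbone N atom"
                    )
                groups.append(ChargedGroup(chain, resnum, res_name,
                                           "NTERM_N", (names["N"],)))
            kind = {"LYS": "LYS_NZ", "ARG": "ARG_GUANIDINIUM"}.get(res_name)
            if kind is None:
                continue
            wanted = _GROUP_ATOMS[kind]
            missing = [a for a in wanted if a not in names]
            if missing:
                raise SelectionError(
                    f"residue {chain}:{resnum} ({res_name}) is missing "
                    f"charged-group atoms {missing}"
                )
            groups.append(ChargedGroup(chain, resnum, res_name, kind,
                                       tuple(names[a] for a in wanted)))
    return groups


def min_distance_series(traj: Trajectory, group_atoms: np.ndarray,
                        site_atoms: np.ndarray) -> np.ndarray:
    """Per-frame minimum distance over all group-atom x site-atom pairs."""
    g = np.asarray(group_atoms, dtype=int)
    s = np.asarray(site_atoms, dtype=int)
    if g.size == 0 or s.size == 0:
        raise SelectionError("contact distance needs non-empty atom sets")
    diff = traj.frames[:, g, None, :] - traj.frames[:, None, s, :]
    return np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))


def residence_frequency(traj: Trajectory, group: ChargedGroup,
                        site_atoms: np.ndarray, cutoff: float = 6.0) -> float:
    """Percentage of frames with min group–site distance strictly < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dmin = min_distance_series(traj, np.array(group.atom_indices), site_atoms)
    return 100.0 * float(np.count_nonzero(dmin < cutoff)) / traj.n_frames


def site_heavy_atoms(structure: Structure, site: tuple[str, int]) -> np.ndarray:
    """All heavy atoms of the damaged-site residue (inclusive reading)."""
    chain, resnum = site
    return select_atoms(structure, chain=chain, residue_number=resnum,
                        heavy_only=True,
                        required=f"heavy atoms of site {chain}:{resnum}")


def contact_table(
    replicate_trajs: dict[str, Trajectory],
    pairs: list[tuple[ChargedGroup, tuple[str, int]]],
    cutoff: float = 6.0,
    decimals: int = 1,
) -> list[ContactSummary]:
    """Table-2-style residence table: one row per (group, site) pair.

    Frequencies are computed per replicate and aggregated by the
    equal-weight "All" convention.  The site label combines the residue
    name and number of the damaged residue (e.g. "K13(P)-AP7").
    """
    if not replicate_trajs:
        raise ValueError("need at least one replicate")
    out = []
    for group, site in pairs:
        per_rep: dict[str, float] = {}
        site_label = None
        for rep, traj in replicate_trajs.items():
            s_idx = site_heavy_atoms(traj.topology, site)
            if site_label is None:
                res_name = str(traj.topology.res_name[s_idx[0]])
                site_label = f"{res_name}{site[1]}"
            freq = residence_frequency(traj, group, s_idx, cutoff)
            per_rep[rep] = round(freq, decimals)
        summary = aggregate_replicates(per_rep, decimals)
        out.append(ContactSummary(f"{group.label}-{site_label}", summary))
    return out
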