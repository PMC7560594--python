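"""Config-driven orchestration: simulate -> analyze -> report.

A run is described by a single structured configuration (YAML/JSON-style
mapping) holding either real trajectory inputs (multi-model PDB files per
replicate) or a synthetic block describing the emulated world, plus the
thresholds and the subset of analyses to run.  ``run_pipeline`` produces a
:class:`ReportBundle` whose numbers equal direct module-call results; the
writers serialize it to CSV tables (extrahelicity/ejection in the
replicate-column layout, contacts likewise), a JSON mirror, and a painted
PDB for the PCA importance map.  Everything is deterministic given the
configuration and seed, and every output records the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contacts import contact_table, find_charged_groups, site_heavy_atoms
from .ensemble import (
    cluster_frames,
    pair_features,
    paint_importance,
    pairwise_rmsd,
    pca_fit,
    residue_importance,
)
from .metrics import (
    ThresholdConfig,
    aggregate_replicates,
    bend_angle_series,
    c1p_distance_series,
    com_distance_series,
    ejection_fraction,
    extrahelicity_percent,
    round_half_away,
)
from .structure import (
    SiteSpec,
    Structure,
    Trajectory,
    extract_section,
    read_structure,
    read_trajectory,
    select_atoms,
    trim_site_spec,
    write_structure,
    write_trajectory,
)
from .synthetic import (
    ContactScript,
    FlipSpec,
    SynthConfig,
    add_tail_probe,
    apply_lesion,
    bend_arc,
    build_bdna,
    duplex_site_spec,
    simulate_flip_dynamics,
    write_ground_truth,
)

log = logging.getLogger("ncpdyn")

ANALYSES = ("extrahelicity", "ejection", "bend", "contacts", "cluster", "pca")

_TOP_KEYS = {"inputs", "synthetic", "thresholds", "analyses", "output_dir",
             "seed", "report_decimals", "trim", "cluster_epsilon",
             "cluster_k", "pca_components"}
_SYN_KEYS = {"sequence", "lesion", "orphan", "n_frames", "noise_sigma",
             "bend_angle", "replicates", "contact_script", "helical_rise",
             "helical_twist"}
_REP_KEYS = {"mode", "fraction", "p_out", "p_in"}


class ConfigError(ValueError):
    """Raised for malformed run configurations."""


@dataclass
class ReplicateKinetics:
    mode: str = "markov"
    fraction: float | None = None
    p_out: float = 0.0
    p_in: float = 0.0


@dataclass
class SyntheticBlock:
    sequence: str
    lesion_position: int
    lesion_type: str = "AP"
    orphan_position: int | None = None
    n_frames: int = 500
    noise_sigma: float = 0.1
    bend_angle: float = 0.0
    helical_rise: float = 3.38
    helical_twist: float = 36.0
    replicates: dict[str, ReplicateKinetics] = field(default_factory=dict)
    contact_script: ContactScript | None = None


@dataclass
class InputBlock:
    topology: str
    replicates: dict[str, str]
    sites: list[SiteSpec]


@dataclass
class RunConfig:
    synthetic: SyntheticBlock | None = None
    inputs: InputBlock | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    analyses: tuple[str, ...] = ANALYSES
    output_dir: str = "ncpdyn_out"
    seed: int = 0
    report_decimals: int = 1
    trim: int = 1
    cluster_epsilon: float | None = 2.5
    cluster_k: int | None = None
    pca_components: int = 10
    config_hash: str = ""


def _require_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {unknown}")


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw configuration mapping and fill defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _require_keys(raw, _TOP_KEYS, "config")
    has_syn = "synthetic" in raw
    has_inp = "inputs" in raw
    if has_syn == has_inp:
        raise ConfigError("exactly one of 'synthetic' or 'inputs' required")

    thresholds = ThresholdConfig(**raw.get("thresholds", {}))
    analyses = tuple(raw.get("analyses", ANALYSES))
    unknown = sorted(set(analyses) - set(ANALYSES))
    if unknown:
        raise ConfigError(f"unknown analyses: {unknown}")

    cfg = RunConfig(
        thresholds=thresholds,
        analyses=analyses,
        output_dir=str(raw.get("output_dir", "ncpdyn_out")),
        seed=int(raw.get("seed", 0)),
        report_decimals=int(raw.get("report_decimals", 1)),
        trim=int(raw.get("trim", 1)),
        cluster_epsilon=raw.get("cluster_epsilon",
                                None if "cluster_k" in raw else 2.5),
        cluster_k=raw.get("cluster_k"),
        pca_components=int(raw.get("pca_components", 10)),
    )

    if has_syn:
        syn = dict(raw["synthetic"])
        _require_keys(syn, _SYN_KEYS, "synthetic")
        lesion = syn.get("lesion")
        if not isinstance(lesion, dict) or "position" not in lesion:
            raise ConfigError("synthetic.lesion needs a 'position'")
        reps = {}
        for name, spec in dict(syn.get("replicates", {"MD1": {}})).items():
            _require_keys(spec, _REP_KEYS, f"synthetic.replicates.{name}")
            reps[name] = ReplicateKinetics(**spec)
        script = None
        if "contact_script" in syn:
            cs = dict(syn["contact_script"])
            script = ContactScript(
                episodes=[tuple(e) for e in cs.pop("episodes")], **cs
            )
        cfg.synthetic = SyntheticBlock(
            sequence=str(syn["sequence"]),
            lesion_position=int(lesion["position"]),
            lesion_type=str(lesion.get("type", "AP")),
            orphan_position=(int(syn["orphan"]["position"])
                             if "orphan" in syn else None),
            n_frames=int(syn.get("n_frames", 500)),
            noise_sigma=float(syn.get("noise_sigma", 0.1)),
            bend_angle=float(syn.get("bend_angle", 0.0)),
            helical_rise=float(syn.get("helical_rise", 3.38)),
            helical_twist=float(syn.get("helical_twist", 36.0)),
            replicates=reps,
            contact_script=script,
        )
    else:
        inp = dict(raw["inputs"])
        _require_keys(inp, {"topology", "replicates", "sites"}, "inputs")
        sites = []
        for s in inp.get("sites", []):
            missing = {"lesion", "facing", "section"} - set(s)
            if missing:
                raise ConfigError(f"site missing fields: {sorted(missing)}")
            from .structure import StrandRange
            sites.append(SiteSpec(
                lesion=tuple(s["lesion"]), facing=tuple(s["facing"]),
                section=tuple(StrandRange(*r) for r in s["section"]),
                orphan=tuple(s["orphan"]) if "orphan" in s else None,
                orphan_partner=(tuple(s["orphan_partner"])
                                if "orphan_partner" in s else None),
                label=s.get("label", "site"),
            ))
        for path in [inp["topology"], *inp["replicates"].values()]:
            if not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")
        cfg.inputs = InputBlock(str(inp["topology"]),
                                {k: str(v) for k, v in
                                 inp["replicates"].items()}, sites)

    canon = json.dumps(raw, sort_keys=True, default=str).encode()
    cfg.config_hash = hashlib.sha256(canon).hexdigest()[:12]
    return cfg


# ---------------------------------------------------------------------------
# Simulation stage
# ---------------------------------------------------------------------------

def build_synthetic_world(cfg: RunConfig) -> tuple[Structure, SiteSpec]:
    """Built lesioned (and optionally bent) duplex plus its site spec."""
    syn = cfg.synthetic
    base_cfg = SynthConfig(
        sequence=syn.sequence, lesion_position=syn.lesion_position,
        lesion_type=syn.lesion_type, orphan_position=syn.orphan_position,
        helical_rise=syn.helical_rise, helical_twist=syn.helical_twist,
        noise_sigma=syn.noise_sigma, seed=cfg.seed, n_frames=syn.n_frames,
    )
    structure = build_bdna(base_cfg)
    spec = duplex_site_spec(base_cfg)
    structure = apply_lesion(structure, spec.lesion, syn.lesion_type)
    if syn.bend_angle:
        structure = bend_arc(structure, syn.bend_angle, rise=syn.helical_rise)
    return structure, spec


def simulate_replicates(cfg: RunConfig) -> tuple[dict[str, Trajectory],
                                                 dict[str, object], SiteSpec]:
    """Per-replicate synthetic trajectories plus ground-truth label tables."""
    syn = cfg.synthetic
    structure, spec = build_synthetic_world(cfg)
    trajs: dict[str, Trajectory] = {}
    labels: dict[str, object] = {}
    for i, (name, kin) in enumerate(sorted(syn.replicates.items())):
        rep_seed = (cfg.seed * 1009 + 7919 * (i + 1)) % (2 ** 31)
        flips = [FlipSpec(site=spec.lesion, mode=kin.mode,
                          fraction=kin.fraction,
                          p_out=kin.p_out, p_in=kin.p_in)]
        if spec.orphan is not None:
            flips.append(FlipSpec(site=spec.orphan, couple_to=spec.lesion,
                                  emission_noise=0.02))
        traj, lab = simulate_flip_dynamics(
            structure, flips, syn.n_frames, seed=rep_seed,
            noise_sigma=syn.noise_sigma,
        )
        if syn.contact_script is not None:
            site_idx = site_heavy_atoms(traj.topology, spec.lesion)
            traj = add_tail_probe(traj, syn.contact_script, site_idx)
        trajs[name] = traj
        labels[name] = lab
        log.info("simulated replicate %s: %d frames, %d atoms",
                 name, traj.n_frames, traj.topology.n_atoms)
    return trajs, labels, spec


def load_replicates(cfg: RunConfig) -> tuple[dict[str, Trajectory], SiteSpec]:
    topo = read_structure(cfg.inputs.topology)
    trajs = {name: read_trajectory(path, topo)
             for name, path in sorted(cfg.inputs.replicates.items())}
    if not cfg.inputs.sites:
        raise ConfigError("inputs mode requires at least one site")
    return trajs, cfg.inputs.sites[0]


# ---------------------------------------------------------------------------
# Analysis stage
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    table1_style: list[dict] = field(default_factory=list)
    table2_style: list[dict] = field(default_factory=list)
    bend_report: list[dict] = field(default_factory=list)
    cluster_report: list[dict] = field(default_factory=list)
    importance_report: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the selected analyses and assemble the report bundle."""
    if cfg.synthetic is not None:
        trajs, _, spec = simulate_replicates(cfg)
        lesion_type = cfg.synthetic.lesion_type
    else:
        trajs, spec = load_replicates(cfg)
        lesion_type = "AP"
    dec = cfg.report_decimals
    bundle = ReportBundle(provenance={
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "version": __version__,
        "n_replicates": len(trajs),
        "analyses": list(cfg.analyses),
    })
    trimmed_spec = trim_site_spec(spec, cfg.trim) if cfg.trim else spec

    if "extrahelicity" in cfg.analyses:
        per = {}
        for name, traj in trajs.items():
            series = c1p_distance_series(traj, spec)
            per[name] = round(extrahelicity_percent(series, cfg.thresholds),
                              dec)
        summary = aggregate_replicates(per, dec)
        bundle.table1_style.append({
            "system": f"{lesion_type} ({spec.label})",
            "metric": "extrahelicity",
            "all": summary.all_mean, **summary.per_replicate,
        })
        log.info("extrahelicity: all=%s", summary.all_mean)

    if "ejection" in cfg.analyses and spec.orphan is not None:
        per = {}
        for name, traj in trajs.items():
            series = com_distance_series(traj, spec.orphan,
                                         spec.orphan_partner)
            per[name] = round(ejection_fraction(series, cfg.thresholds), dec)
        summary = aggregate_replicates(per, dec)
        bundle.table1_style.append({
            "system": f"orphan {spec.orphan[0]}:{spec.orphan[1]}",
            "metric": "ejection",
            "all": summary.all_mean, **summary.per_replicate,
        })
        log.info("ejection: all=%s", summary.all_mean)

    if "bend" in cfg.analyses:
        for name, traj in trajs.items():
            angles = bend_angle_series(traj, trimmed_spec)
            bundle.bend_report.append({
                "replicate": name,
                "mean_deg": round_half_away(angles.mean, dec),
                "std_deg": round_half_away(angles.std, dec),
                "note": "simplified end-segment axis fit",
            })
        log.info("bend angles computed for %d replicates", len(trajs))

    if "contacts" in cfg.analyses:
        probe_chains = sorted(
            {str(c) for t in trajs.values() for c in t.topology.chain_id}
            - {"A", "B"}
        )
        if probe_chains:
            topo0 = next(iter(trajs.values())).topology
            groups = find_charged_groups(topo0, probe_chains)
            pairs = [(g, spec.lesion) for g in groups]
            for row in contact_table(trajs, pairs,
                                     cutoff=cfg.thresholds.contact_cutoff,
                                     decimals=dec):
                bundle.table2_style.append({
                    "pair": row.pair_label, "all": row.all_mean,
                    **row.per_replicate,
                })
            log.info("contacts: %d pairs", len(pairs))

    if "cluster" in cfg.analyses:
        for name, traj in trajs.items():
            section = extract_section(traj, spec, cfg.trim)
            sel = select_atoms(section.topology, chain=("A", "B"),
                               heavy_only=True)
            mat = pairwise_rmsd(section, sel,
                                f"heavy atoms, {trimmed_spec.n_bp}-bp section")
            result = cluster_frames(mat, epsilon=cfg.cluster_epsilon,
                                    k=cfg.cluster_k)
            occ = {int(c): round(p, dec)
                   for c, p in sorted(result.occupancy.items(),
                                      key=lambda kv: -kv[1])}
            bundle.cluster_report.append({
                "replicate": name, "occupancy_percent": occ,
                "medoid_frame": {int(c): int(m)
                                 for c, m in result.medoid.items()},
            })
            log.info("cluster %s: occupancies %s", name, occ)

    if "pca" in cfg.analyses:
        a_rng, b_rng = trimmed_spec.section
        residues = (
            [(a_rng.chain, r) for r in range(a_rng.start, a_rng.end + 1)]
            + [(b_rng.chain, r) for r in range(b_rng.start, b_rng.end + 1)]
        )
        for name, traj in trajs.items():
            feats, pairs = pair_features(traj, residues)
            model = pca_fit(feats, pairs)
            n_comp = min(cfg.pca_components, model.n_components)
            imp = residue_importance(model, n_comp)
            bundle.importance_report.append({
                "replicate": name,
                "n_components": n_comp,
                "importance_percent": {
                    f"{c}:{r}": round(v, 2)
                    for (c, r), v in sorted(imp.per_residue.items())
                },
            })
            log.info("pca %s: %d features, %d components",
                     name, feats.shape[1], n_comp)

    return bundle


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def _fmt(v: float, dec: int) -> str:
    return f"{v:.{dec}f}"


def write_bundle(bundle: ReportBundle, out_dir: str | Path,
                 decimals: int = 1,
                 painted: tuple[Structure, dict] | None = None) -> list[Path]:
    """Write the bundle as CSV tables plus a JSON mirror.

    Outputs are byte-deterministic for a given bundle.  Every file carries
    the configuration hash and seed in a comment header.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    head = (f"# ncpdyn v{bundle.provenance.get('version', '?')} "
            f"config={bundle.provenance.get('config_hash', '?')} "
            f"seed={bundle.provenance.get('seed', '?')}\n")
    written: list[Path] = []

    if bundle.table1_style:
        reps = sorted({k for row in bundle.table1_style
                       for k in row if k not in ("system", "metric", "all")})
        path = out / "table1_extrahelicity.csv"
        with path.open("w") as fh:
            fh.write(head)
            fh.write("System,Metric,All (%)," +
                     ",".join(f"{r} (%)" for r in reps) + "\n")
            for row in bundle.table1_style:
                fh.write(",".join([row["system"], row["metric"],
                                   _fmt(row["all"], decimals)] +
                                  [_fmt(row[r], decimals) for r in reps])
                         + "\n")
        written.append(path)

    if bundle.table2_style:
        reps = sorted({k for row in bundle.table2_style
                       for k in row if k not in ("pair", "all")})
        path = out / "table2_contacts.csv"
        with path.open("w") as fh:
            fh.write(head)
            fh.write("Interaction,All (%)," +
                     ",".join(f"{r} (%)" for r in reps) + "\n")
            for row in bundle.table2_style:
                fh.write(",".join([row["pair"], _fmt(row["all"], decimals)] +
                                  [_fmt(row[r], decimals) for r in reps])
                         + "\n")
        written.append(path)

    path = out / "bundle.json"
    with path.open("w") as fh:
        json.dump(bundle.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)
    return written
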