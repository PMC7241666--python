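"""Multi-condition analysis orchestration and report generation.

``run_analysis`` executes every stage on each condition's trajectory —
RMSD / radius-of-gyration / SASA series with converged-window statistics,
hydrogen-bond records and category means, salt bridges, hydrophobic
contacts, monitored atom-pair distances, RMSF profiles — then compares
conditions: one-way ANOVA on the per-frame metrics, differential
interaction classification, and thermal-sensitive region calls against the
reference (first) condition.  All outputs are plain CSV/JSON with
deterministic ordering, plus a JSON echo of the fully-resolved
configuration so every defaulted parameter is visible per run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from thermotraj import geometry, hbonds, interactions, regions, sasa
from thermotraj.occupancy import differential_classify
from thermotraj.io import (
    TrajectoryFileSpec,
    read_pdb,
    read_trajectory,
    write_records,
)
from thermotraj.model import CATALYTIC_RESIDUES, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis parameters; defaults are the standard criteria."""

    conditions: list[dict] = field(default_factory=list)
    # each: {label, topology (pdb path), trajectory (path), format, stride,
    #        time_step}
    hbond_distance_cutoff: float = 3.5  # Angstrom, inclusive
    hbond_angle_cutoff: float = 120.0  # degrees at H, strict
    saltbridge_cutoff: float = 4.0  # Angstrom, strict
    contact_cutoff: float = 4.0  # Angstrom, inclusive
    occupancy_filter: float = 50.0  # strict > for stable-interaction tables
    region_thresholds: tuple[float, float] = (0.5, 1.0)  # Angstrom
    region_min_length: int = 3
    region_max_gap: int = 1
    region_exclude_termini: int = 5
    comparability_tol: float = 10.0
    maintained_floor: float = 80.0
    converged_window: tuple[float, float] = (0.25, 1.0)
    catalytic_residues: list[int] = field(
        default_factory=lambda: sorted(CATALYTIC_RESIDUES)
    )
    monitored_pairs: list[dict] = field(default_factory=list)
    # each: {res_a, atom_a, res_b, atom_b, threshold}
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    sasa_frame_stride: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.region_thresholds = tuple(cfg.region_thresholds)
        cfg.converged_window = tuple(cfg.converged_window)
        return cfg


CONDITION_TABLES = (
    "rmsd_series.csv",
    "rg_series.csv",
    "sasa_series.csv",
    "summary.csv",
    "hbond_records.csv",
    "hbond_counts.csv",
    "saltbridge_records.csv",
    "contact_records.csv",
    "rmsf_profile.csv",
    "sasa_distribution.csv",
)


def analyze_condition(trajectory: Trajectory, config: RunConfig,
                      out_dir: str | Path) -> dict:
    """Run every per-condition stage and write its tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = config.converged_window
    results: dict = {"label": trajectory.condition_label}

    stage = "rmsd"
    try:
        rmsd_df, rmsd_mean, rmsd_sd = geometry.rmsd_series(
            trajectory, "backbone", window=window
        )
        rmsd_df.to_csv(out / "rmsd_series.csv", index=False, float_format="%.4f")

        stage = "rg"
        rg_df, rg_mean, rg_sd = geometry.rg_series(trajectory, "protein", window=window)
        rg_df.to_csv(out / "rg_series.csv", index=False, float_format="%.4f")

        stage = "sasa"
        sasa_traj = trajectory
        if config.sasa_frame_stride > 1:
            frames = trajectory.frames[:: config.sasa_frame_stride]
            sasa_traj = Trajectory(
                trajectory.topology, frames, trajectory.condition_label
            )
        sasa_df, sasa_summary = sasa.sasa_series(
            sasa_traj,
            config.sasa_probe_radius,
            config.sasa_n_points,
            set(config.catalytic_residues),
            window=window,
        )
        sasa_df.to_csv(out / "sasa_series.csv", index=False, float_format="%.4f")
        dist = sasa.sasa_distribution(sasa_df["sasa_total"].to_numpy())
        pd.DataFrame(
            {"bin_center_nm2": dist.bin_centers, "count": dist.counts}
        ).to_csv(out / "sasa_distribution.csv", index=False, float_format="%.4f")

        stage = "hbonds"
        candidates = hbonds.detect_hbonds(
            trajectory, config.hbond_distance_cutoff, config.hbond_angle_cutoff
        )
        records = hbonds.classify_hbonds(
            hbonds.dedupe_hbonds(candidates, trajectory.topology),
            trajectory.topology,
        )
        hb_rows = [
            {
                "donor_res": r.donor_residue,
                "donor_atom": r.donor_atom,
                "acceptor_res": r.acceptor_residue,
                "acceptor_atom": r.acceptor_atom,
                "occupancy_pct": r.occupancy,
                "backbone_class": r.backbone_class,
                "chem_class": r.chem_class,
                "partner_kind": r.partner_kind,
                "water_class": r.water_class,
            }
            for r in records
        ]
        write_records(
            hb_rows,
            out / "hbond_records.csv",
            sort_by=["donor_res", "donor_atom", "acceptor_res", "acceptor_atom"],
            columns=["donor_res", "donor_atom", "acceptor_res", "acceptor_atom",
                     "occupancy_pct", "backbone_class", "chem_class",
                     "partner_kind", "water_class"],
        )
        counts = hbonds.mean_hbond_counts(records)
        count_rows = [
            {"table": table, "category": cat, "mean_count": val}
            for table in ("protein", "water")
            for cat, val in counts[table].items()
        ]
        write_records(count_rows, out / "hbond_counts.csv")

        stage = "saltbridges"
        sb_events = interactions.detect_salt_bridges(
            trajectory, config.saltbridge_cutoff
        )
        sb_records = interactions.unique_salt_bridges(sb_events, trajectory.topology)
        sb_rows = [
            {
                "pair": r.pair_label,
                "acidic_atom": r.acidic_atom,
                "basic_atom": r.basic_atom,
                "occupancy_pct": r.occupancy,
                "union_occupancy_pct": r.union_occupancy,
                "mean_dist": r.mean_distance,
                "sd_dist": r.sd_distance,
            }
            for r in sb_records
        ]
        write_records(
            sb_rows, out / "saltbridge_records.csv", sort_by=["pair"],
            columns=["pair", "acidic_atom", "basic_atom", "occupancy_pct",
                     "union_occupancy_pct", "mean_dist", "sd_dist"],
        )

        stage = "contacts"
        contact_records = interactions.detect_hydrophobic_contacts(
            trajectory, config.contact_cutoff
        )
        contact_rows = [
            {
                "res_a": r.residue_a,
                "res_b": r.residue_b,
                "atom_a": r.atom_a,
                "atom_b": r.atom_b,
                "occupancy_pct": r.occupancy,
            }
            for r in contact_records
        ]
        write_records(
            contact_rows, out / "contact_records.csv", sort_by=["res_a", "res_b"],
            columns=["res_a", "res_b", "atom_a", "atom_b", "occupancy_pct"],
        )

        stage = "monitors"
        for mp in config.monitored_pairs:
            mon = interactions.monitor_distance(
                trajectory,
                (mp["res_a"], mp["atom_a"]),
                (mp["res_b"], mp["atom_b"]),
                mp.get("threshold", 3.5),
            )
            name = f"monitor_{mp['res_a']}{mp['atom_a']}_{mp['res_b']}{mp['atom_b']}.csv"
            mon.series.to_csv(out / name, index=False, float_format="%.4f")
            results.setdefault("monitors", {})[name] = mon.fraction_below

        stage = "rmsf"
        profile = geometry.rmsf_profile(trajectory, "backbone", "backbone")
        profile.to_frame().to_csv(
            out / "rmsf_profile.csv", index=False, float_format="%.4f"
        )

        stage = "summary"
        summary_rows = [
            {"metric": "rmsd_backbone_A", "mean": rmsd_mean, "sd": rmsd_sd},
            {"metric": "rg_A", "mean": rg_mean, "sd": rg_sd},
            {"metric": "sasa_total_nm2", "mean": sasa_summary["sasa_total"][0],
             "sd": sasa_summary["sasa_total"][1]},
            {"metric": "sasa_pho_nm2", "mean": sasa_summary["sasa_pho"][0],
             "sd": sasa_summary["sasa_pho"][1]},
            {"metric": "sasa_phil_nm2", "mean": sasa_summary["sasa_phil"][0],
             "sd": sasa_summary["sasa_phil"][1]},
            {"metric": "sasa_catalytic_A2", "mean": sasa_summary["sasa_catalytic"][0],
             "sd": sasa_summary["sasa_catalytic"][1]},
        ]
        write_records(summary_rows, out / "summary.csv")
    except Exception:
        logger.exception("condition %r failed at stage %r",
                         trajectory.condition_label, stage)
        raise RuntimeError(
            f"analysis of condition {trajectory.condition_label!r} failed "
            f"at stage {stage!r}"
        )

    results.update(
        rmsd=(rmsd_mean, rmsd_sd),
        rg=(rg_mean, rg_sd),
        sasa=sasa_summary,
        sasa_peak=(dist.peak_center, dist.peak_percent),
        rmsd_values=rmsd_df["rmsd"].to_numpy(),
        rg_values=rg_df["rg"].to_numpy(),
        sasa_values=sasa_df["sasa_total"].to_numpy(),
        hbond_records=records,
        saltbridge_records=sb_records,
        contact_records=contact_records,
        rmsf=profile,
    )
    return results


def compare_conditions(per_condition: dict[str, dict], config: RunConfig,
                       out_dir: str | Path) -> dict:
    """Cross-condition ANOVA, differential calls, and region calls."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = list(per_condition)
    if len(labels) < 2:
        return {}
    reference = labels[0]

    anova_rows = []
    for metric_key, name in (
        ("rmsd_values", "rmsd"),
        ("rg_values", "rg"),
        ("sasa_values", "sasa_total"),
    ):
        for other in labels[1:]:
            res = regions.one_way_anova(
                [per_condition[reference][metric_key], per_condition[other][metric_key]]
            )
            anova_rows.append(
                {
                    "metric": name,
                    "comparison": f"{other}/{reference}",
                    "F": res.f_statistic,
                    "df1": res.df_between,
                    "df2": res.df_within,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
    write_records(anova_rows, out / "anova.csv")

    diff_results = {}
    for kind, record_key, id_fn in (
        ("saltbridges", "saltbridge_records", lambda r: r.pair_label),
        ("hbonds", "hbond_records",
         lambda r: f"{r.donor_residue}{r.donor_atom}-{r.acceptor_residue}{r.acceptor_atom}"),
        ("contacts", "contact_records", lambda r: r.pair_label),
    ):
        by_cond = {
            label: {id_fn(r): r.occupancy for r in per_condition[label][record_key]}
            for label in labels
        }
        calls = differential_classify(
            by_cond,
            labels,
            comparability_tol=config.comparability_tol,
            maintained_floor=config.maintained_floor,
            presence_threshold=config.occupancy_filter,
        )
        rows = [
            {
                "interaction_id": c.interaction_id,
                **{f"occ_{label}": (c.occupancies[label] if c.occupancies[label]
                                    is not None else float("nan"))
                   for label in labels},
                "call": c.call,
            }
            for c in calls
        ]
        write_records(rows, out / f"differential_{kind}.csv",
                      sort_by=["interaction_id"] if rows else None,
                      columns=["interaction_id",
                               *[f"occ_{label}" for label in labels], "call"])
        diff_results[kind] = calls

    region_results = {}
    ref_profile = per_condition[reference]["rmsf"]
    for other in labels[1:]:
        delta = regions.delta_rmsf(per_condition[other]["rmsf"], ref_profile)
        calls = regions.call_regions(
            delta,
            thresholds=config.region_thresholds,
            min_length=config.region_min_length,
            max_gap=config.region_max_gap,
            exclude_termini=config.region_exclude_termini,
        )
        rows = [
            {
                "start": c.start_residue_seq,
                "end": c.end_residue_seq,
                "mean_delta": c.mean_delta,
                "max_delta": c.max_delta,
                "flag_level": c.flag_level,
            }
            for c in calls
        ]
        write_records(rows, out / f"regions_{other}_vs_{reference}.csv",
                      columns=["start", "end", "mean_delta", "max_delta",
                               "flag_level"])
        region_results[other] = calls

    return {"anova": anova_rows, "differential": diff_results,
            "regions": region_results}


def run_analysis(config: RunConfig, out_dir: str | Path) -> dict:
    """Load every condition, run all stages, and write the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=str)
        fh.write("\n")

    per_condition: dict[str, dict] = {}
    for cond in config.conditions:
        label = cond["label"]
        logger.info("analyzing condition %s", label)
        topology, _ = read_pdb(cond["topology"])
        spec = TrajectoryFileSpec(
            path=cond["trajectory"],
            format=cond.get("format", "xyz_frames"),
            stride=cond.get("stride", 1),
            time_step=cond.get("time_step", 10.0),
        )
        trajectory = read_trajectory(spec, topology)
        trajectory.condition_label = label
        per_condition[label] = analyze_condition(trajectory, config, out / label)

    comparison = compare_conditions(per_condition, config, out)
    return {"conditions": per_condition, "comparison": comparison}
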