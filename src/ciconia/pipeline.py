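"""End-to-end pipeline: simulate -> io -> segmentation -> metrics -> stats.

Each stage is a plain function over files/tables so stages can be re-run
individually (the CLI exposes them as subcommands); :func:`run` chains
them into one deterministic, manifest-logged run.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, simulate
from .flightmetrics import attach_behaviour, glide_airspeeds
from .migration import (
    MigrationParams, ReleaseInfo, daily_summaries, migration_summary,
    summaries_table,
)
from .segmentation import (
    CLIMBING, GLIDING, SegmentationParams, bouts_table, segment_burst,
    thermal_exit_altitudes,
)
from .stats import fisher_exact, kruskal_wallis, pairwise_fisher_bh, pairwise_wilcoxon_bh

__version__ = "0.1.0"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "ciconia-run"
    sim: simulate.SimConfig = field(default_factory=simulate.default_config)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    mig: MigrationParams = field(default_factory=MigrationParams)
    gap_threshold_s: float = 30.0

    def validate(self) -> None:
        self.sim.validate()
        self.seg.validate()
        self.mig.validate()


@dataclass
class RunResult:
    out_dir: Path
    bursts: list
    flight_bouts_by_burst: dict
    climb_bouts: list
    glide_bouts: list
    odba: pd.DataFrame
    daily: pd.DataFrame
    individuals: pd.DataFrame
    stats: dict
    labels: pd.DataFrame
    release: pd.DataFrame


def segment_all(bursts, seg_params):
    """Segment every burst -> (flight map by id(burst), climbs, glides)."""
    flight_by_burst: dict[int, list] = {}
    climbs, glides = [], []
    for b in bursts:
        f, c, g = segment_burst(b, seg_params)
        flight_by_burst[id(b)] = f
        climbs.extend(c)
        glides.extend(g)
    return flight_by_burst, climbs, glides


def segmentation_accuracy(bursts, climbs, glides, labels: pd.DataFrame) -> float:
    """Per-fix accuracy of climbing/gliding recovery against truth labels.

    Scores only fixes whose hidden truth label is climb or glide; the
    predicted class comes from bout membership (fix i belongs to the bout
    covering derived index i-1). Assumes bursts were assembled from a
    simulated cohort so burst_index aligns with emission order.
    """
    by_ind: dict[str, list] = {}
    for b in bursts:
        by_ind.setdefault(b.individual_id, []).append(b)
    for lst in by_ind.values():
        lst.sort(key=lambda b: b.start_time)

    bouts_by_burst: dict[tuple, list] = {}
    for bout in list(climbs) + list(glides):
        bouts_by_burst.setdefault(
            (bout.individual_id, np.datetime64(bout.burst_start_time, "ns")), []
        ).append(bout)

    n_ok = n_tot = 0
    for (ind, bidx), sub in labels.groupby(["individual_id", "burst_index"]):
        cand = by_ind.get(str(ind))
        if cand is None or bidx >= len(cand):
            continue
        burst = cand[int(bidx)]
        pred = np.full(burst.n, "other", dtype=object)
        for bout in bouts_by_burst.get(
            (burst.individual_id, np.datetime64(burst.start_time, "ns")), ()
        ):
            kind = "climb" if bout.kind == CLIMBING else "glide"
            pred[bout.start_idx + 1:bout.end_idx + 2] = kind
        truth = sub.sort_values("fix_index")["label"].to_numpy()
        m = min(truth.size, burst.n)
        keep = np.isin(truth[:m], ("climb", "glide"))
        n_tot += int(keep.sum())
        n_ok += int((pred[:m][keep] == truth[:m][keep]).sum())
    return n_ok / n_tot if n_tot else float("nan")


def behaviour_accuracy(odba: pd.DataFrame, labels: pd.DataFrame, bursts) -> float:
    """Agreement between ACC-burst behaviour and truth at GPS-burst ends."""
    by_ind: dict[str, list] = {}
    for b in bursts:
        by_ind.setdefault(b.individual_id, []).append(b)
    for lst in by_ind.values():
        lst.sort(key=lambda b: b.start_time)

    last_label = {}
    for (ind, bidx), sub in labels.groupby(["individual_id", "burst_index"]):
        lab = sub.sort_values("fix_index")["label"].iloc[-1]
        cand = by_ind.get(str(ind))
        if cand is None or bidx >= len(cand):
            continue
        end_t = pd.Timestamp(cand[int(bidx)].end_time)
        last_label[(str(ind), end_t)] = lab

    n_ok = n_tot = 0
    for r in odba.itertuples(index=False):
        # the ACC burst fires 1 s after its GPS burst ends
        key = (str(r.individual_id), pd.Timestamp(r.t) - pd.Timedelta(seconds=1))
        truth = last_label.get(key)
        if truth in ("climb", "glide"):
            n_tot += 1
            want = "climbing" if truth == "climb" else "gliding"
            n_ok += int(r.behaviour == want)
    return n_ok / n_tot if n_tot else float("nan")


def group_stats(individuals: pd.DataFrame, daily: pd.DataFrame | None = None) -> dict:
    """Contingency and rank statistics across study groups."""
    out: dict = {}
    groups = list(dict.fromkeys(individuals["group"]))
    prop = []
    for g in groups:
        sub = individuals[individuals["group"] == g]
        prop.append([int(sub["migratory"].sum()), int((~sub["migratory"]).sum())])
    out["propensity_table"] = {"groups": groups, "counts": prop}
    out["propensity_fisher_p"] = fisher_exact(prop)
    if len(groups) >= 3:
        out["propensity_pairwise"] = pairwise_fisher_bh(prop, row_labels=groups).as_dict()

    days = [
        individuals.loc[
            (individuals["group"] == g) & individuals["days_in_segment"].notna(),
            "days_in_segment",
        ].to_numpy()
        for g in groups
    ]
    if all(d.size > 0 for d in days):
        H, df, p = kruskal_wallis(days)
        out["days_in_segment_kw"] = {"H": H, "df": df, "p": p}
        out["days_in_segment_pairwise"] = pairwise_wilcoxon_bh(days, labels=groups).as_dict()
    return out


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline into ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = config.sim
    sim = simulate.simulate_cohort(cfg)
    simulate.write_movebank_csv(sim.gps, out / "gps.csv")
    io.write_acc_csv(sim.acc, out / "acc.csv")
    simulate.write_labels_csv(sim.labels, out / "labels.csv")
    sim.release.to_csv(out / "release.csv", index=False, lineterminator="\n")

    fixes, report = io.read_movebank(out / "gps.csv")
    bursts = io.assemble_bursts(fixes, gap_threshold_s=config.gap_threshold_s)
    for b in bursts:
        io.derive_kinematics(b)

    flight_by_burst, climbs, glides = segment_all(bursts, config.seg)
    all_bouts = [fb for lst in flight_by_burst.values() for fb in lst] + climbs + glides
    bouts_table(all_bouts).to_csv(out / "bouts.csv", index=False, lineterminator="\n")

    acc = io.read_acc(out / "acc.csv")
    odba = attach_behaviour(acc, bursts, climbs, glides)
    odba.to_csv(out / "odba.csv", index=False, lineterminator="\n")

    daily = daily_summaries(bursts, flight_by_burst, config.mig)
    daily.to_csv(out / "daily.csv", index=False, lineterminator="\n")

    by_ind: dict[str, list] = {}
    for b in bursts:
        by_ind.setdefault(b.individual_id, []).append(b)
    summaries = []
    for r in sim.release.itertuples(index=False):
        track = by_ind.get(r.individual_id, [])
        if not track:
            continue
        rel = ReleaseInfo(
            individual_id=r.individual_id,
            date=pd.Timestamp(r.release_date).date(),
            lat=r.lat, lon=r.lon, released=bool(r.released),
        )
        summaries.append(migration_summary(
            track, rel, config.mig, group=r.group, daily=daily,
        ))
    individuals = summaries_table(summaries)
    individuals.to_csv(out / "individuals.csv", index=False, lineterminator="\n")

    stats = group_stats(individuals, daily)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=float)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "sim": _jsonable(asdict(cfg)),
            "segmentation": asdict(config.seg),
            "migration": asdict(config.mig),
            "gap_threshold_s": config.gap_threshold_s,
        },
        "rows": {
            "gps": int(len(sim.gps)),
            "acc": int(len(sim.acc)),
            "rejected_gps_rows": int(len(report)),
            "bursts": len(bursts),
            "bouts": len(all_bouts),
            "daily": int(len(daily)),
            "individuals": int(len(individuals)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(
        out_dir=out,
        bursts=bursts,
        flight_bouts_by_burst=flight_by_burst,
        climb_bouts=climbs,
        glide_bouts=glides,
        odba=odba,
        daily=daily,
        individuals=individuals,
        stats=stats,
        labels=sim.labels,
        release=sim.release,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ------------------------------------------------- evaluation conveniences

def recovered_climb_rates(climb_bouts) -> np.ndarray:
    return np.array([b.mean_raw_climb_rate for b in climb_bouts])


def recovered_glide_airspeeds(bursts, glide_bouts) -> np.ndarray:
    by_key: dict[tuple, list] = {}
    for g in glide_bouts:
        by_key.setdefault((g.individual_id, np.datetime64(g.burst_start_time, "ns")), []).append(g)
    out = []
    for b in bursts:
        key = (b.individual_id, np.datetime64(b.start_time, "ns"))
        if key in by_key:
            out.append(glide_airspeeds(b, by_key[key]))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def recovered_exit_altitudes(climb_bouts, seg_params) -> np.ndarray:
    return np.array(thermal_exit_altitudes(climb_bouts, seg_params))


def bouts_for_group(bouts, individuals_of_group) -> list:
    ids = set(individuals_of_group)
    return [b for b in bouts if b.individual_id in ids]
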