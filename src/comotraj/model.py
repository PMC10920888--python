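"""Model/Results facade over the trajectory pipeline.

:class:`ComorbidityTrajectoryModel` is built from hospital-stay records
(or a simulation config) and ``fit()`` runs the whole estimation chain —
wash-out, diagnosis events, multilayer network construction, overlapping
community detection, trajectory classification, outcomes and critical
events — returning a :class:`TrajectoryResults` carrying every estimate
plus a ``summary()`` table, artifact export and plotting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .communities import DetectionConfig, communities_to_jsonl, detect_all
from .network import BuilderConfig, build_network, network_summary
from .outcomes import (
    OutcomeData,
    compute_outcomes,
    detect_critical_events,
)
from .records import (
    CohortConfig,
    apply_washout,
    read_stays,
    stays_frame,
    to_events,
    write_stays,
)
from .trajectories import (
    classify_all,
    communities_to_trajectories,
    relations_frame,
    trajectory_stats,
)


class ComorbidityTrajectoryModel:
    """Disease-trajectory estimation on one sex stratum of a registry."""

    def __init__(self, stays, sex: str = "male",
                 cohort: CohortConfig = CohortConfig(),
                 builder: BuilderConfig = BuilderConfig(),
                 detection: DetectionConfig = DetectionConfig(),
                 critical_threshold: float = 1.5,
                 min_stay_days: int = 1):
        self.stays = list(stays)
        self.sex = sex
        self.cohort = cohort
        self.builder = builder
        self.detection = detection
        self.critical_threshold = critical_threshold
        self.min_stay_days = min_stay_days
        self.ground_truth = None

    @classmethod
    def from_csv(cls, path, schema=None, **kwargs):
        stays, rejects = read_stays(path, schema)
        model = cls(stays, **kwargs)
        model.rejects = rejects
        return model

    @classmethod
    def from_simulation(cls, sim_config, **kwargs):
        from .simulate import simulate_cohort

        stays, gt = simulate_cohort(sim_config)
        model = cls(stays, **kwargs)
        model.ground_truth = gt
        return model

    def fit(self, compute_summary: bool = True) -> "TrajectoryResults":
        cohort_ids, kept = apply_washout(self.stays, self.cohort)
        events = to_events(kept, self.cohort)
        net, audits = build_network(events, self.builder, self.sex)
        communities = detect_all(net, self.detection)
        trajectories = communities_to_trajectories(
            [c.members for c in communities]
        )
        relations, counts = classify_all(trajectories)
        ev_sex = events[events["sex"] == self.sex]
        st = stays_frame(kept)
        st_sex = st[st["sex"] == self.sex]
        data = OutcomeData(ev_sex, st_sex, self.min_stay_days)
        outcomes = compute_outcomes(trajectories, data)
        critical = detect_critical_events(
            relations, outcomes, trajectories, self.critical_threshold
        )
        net_summary, per_layer = (
            network_summary(net) if compute_summary else ({}, pd.DataFrame())
        )
        return TrajectoryResults(
            model=self, cohort_ids=cohort_ids, events=events, network=net,
            audits=audits, communities=communities, trajectories=trajectories,
            relations=relations, relation_counts=counts, outcomes=outcomes,
            critical_events=critical, net_summary=net_summary,
            per_layer_summary=per_layer, outcome_data=data,
        )


class TrajectoryResults:
    """Fitted pipeline results with export and reporting helpers."""

    def __init__(self, model, cohort_ids, events, network, audits,
                 communities, trajectories, relations, relation_counts,
                 outcomes, critical_events, net_summary, per_layer_summary,
                 outcome_data):
        self.model = model
        self.cohort_ids = cohort_ids
        self.events = events
        self.network = network
        self.audits = audits
        self.communities = communities
        self.trajectories = trajectories
        self.relations = relations
        self.relation_counts = relation_counts
        self.outcomes = outcomes
        self.critical_events = critical_events
        self.net_summary = net_summary
        self.per_layer_summary = per_layer_summary
        self.outcome_data = outcome_data

    @property
    def flagged_critical_events(self):
        return [e for e in self.critical_events if e.flagged]

    def summary(self) -> str:
        lines = [
            "Comorbidity trajectory model".center(64),
            "=" * 64,
            f"sex stratum:        {self.model.sex}",
            f"cohort patients:    {len(self.cohort_ids)}",
            f"diagnosis events:   {len(self.events)}",
            f"network nodes:      {self.network.graph.number_of_nodes()}",
            f"intralayer links:   {len(self.network.intralayer_links)}",
            f"interlayer links:   {len(self.network.interlayer_links)}",
            f"trajectories:       {len(self.trajectories)}",
            f"critical events:    {len(self.flagged_critical_events)} flagged "
            f"of {len(self.critical_events)} diverging pairs",
            "-" * 64,
            "pair relations (exclusive counts):",
        ]
        for label, row in self.relation_counts.iterrows():
            lines.append(f"  {label:<12} {row['exclusive']:>6}")
        if self.net_summary:
            lines.append("-" * 64)
            lines.append("network properties:")
            for k, v in self.net_summary.items():
                if isinstance(v, float):
                    lines.append(f"  {k:<32} {v:10.4f}")
                else:
                    lines.append(f"  {k:<32} {v!s:>10}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write every artifact plus a reproducibility manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stays(self.model.stays, outdir / "stays.csv")
        self.events.to_csv(outdir / "events.csv", index=False)
        self.network.to_graphml(outdir / "network.graphml")
        self.network.edge_list().to_csv(outdir / "edges.tsv", sep="\t",
                                        index=False)
        self.audits["intralayer"].to_csv(
            outdir / "associations_intralayer.csv", index=False)
        self.audits["interlayer"].to_csv(
            outdir / "associations_interlayer.csv", index=False)
        communities_to_jsonl(self.communities, outdir / "communities.jsonl")
        with open(outdir / "trajectories.json", "w") as fh:
            json.dump(trajectories_payload(self.trajectories), fh, indent=1)
        relations_frame(self.relations).to_csv(
            outdir / "relations.csv", index=False)
        self.relation_counts.to_csv(outdir / "relation_counts.csv")
        self.outcomes.drop(columns=["m_by_code"]).to_csv(
            outdir / "outcomes.csv", index=False)
        with open(outdir / "critical_events.json", "w") as fh:
            json.dump([
                {
                    "x_id": e.x_id, "y_id": e.y_id,
                    "split_layer": e.split_layer, "flagged": e.flagged,
                    "ratios": e.ratios.to_dict(orient="records"),
                }
                for e in self.critical_events
            ], fh, indent=1)
        manifest = {
            "version": __version__,
            "sex": self.model.sex,
            "config": {
                "cohort": asdict(self.model.cohort),
                "builder": asdict(self.model.builder),
                "detection": asdict(self.model.detection),
                "critical_threshold": self.model.critical_threshold,
                "min_stay_days": self.model.min_stay_days,
            },
            "config_hash": self.network.provenance["config_hash"],
            "input_hash": input_hash(self.model.stays),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return outdir

    def plot_trajectory_stats(self):
        """Four-panel figure: size distribution, chapters, pairwise
        Jaccard histogram, relation frequencies."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        stats = trajectory_stats(self.trajectories)
        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        stats["size"].plot.bar(ax=axes[0, 0], title="trajectory size")
        stats["age_span"].plot.bar(ax=axes[0, 1], title="age-group span")
        if len(stats["jaccard"]):
            axes[1, 0].hist(stats["jaccard"], bins=20)
        axes[1, 0].set_title("pairwise Jaccard")
        self.relation_counts["exclusive"].plot.bar(
            ax=axes[1, 1], title="pair relations")
        fig.tight_layout()
        return fig


def trajectories_payload(trajectories):
    from ._icd import node_label

    return {
        "schema_version": 1,
        "trajectories": [
            {
                "id": t.id,
                "tuples": sorted(node_label(c, a) for c, a in t.tuples),
                "size": t.size,
                "age_span": t.age_span,
                "n_codes": t.n_codes,
                "n_chapters": t.n_chapters,
            }
            for t in trajectories
        ],
    }


def input_hash(stays) -> str:
    h = hashlib.sha1()
    for s in stays:
        h.update(repr((s.patient_id, s.sex, s.age_band, s.admission_date,
                       s.release_date, s.release_type, s.diagnoses)).encode())
    return h.hexdigest()[:12]
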