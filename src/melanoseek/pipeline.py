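"""End-to-end orchestration of the repurposing cascade, plus report checks.

``run_pipeline`` drives the stage sequence ingest → integrate → metnet →
map → exclude → pathofilter → connectivity → select over a fixture directory
(the layout written by :mod:`melanoseek.synthetic`, equally usable with real
catalog exports in the same dialects) and emits a :class:`PipelineReport`
with per-stage drug/target counts and the final candidate list with
connectivity scores.

``table1_checks`` computes summary counts over the packaged transcription of
the published 35-drug candidate table (drugs, unique targets, literature
evidence, and a concordance tally under both policies).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import evidence_io, integration, metnet, pharm
from .connectivity import (
    TagSet,
    aggregate_drugs,
    connectivity_scores,
    read_signature_panel,
    read_tagset,
    select_candidates,
    write_results,
)
from .synthetic import ANCHORS_NEG, ANCHORS_POS
from .types import Action, Direction, Policy, Source, Verdict

logger = logging.getLogger("melanoseek.pipeline")

PathLike = Union[str, Path]

STAGES = (
    "ingest", "integrate", "metnet", "map", "exclude", "pathofilter",
    "connectivity", "select",
)


@dataclass
class StageCount:
    stage: str
    drugs: Optional[int] = None
    targets: Optional[int] = None


@dataclass
class PipelineReport:
    stage_counts: list[StageCount] = field(default_factory=list)
    candidates: list[dict] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage_counts": [
                {"stage": s.stage, "drugs": s.drugs, "targets": s.targets}
                for s in self.stage_counts
            ],
            "candidates": self.candidates,
            "config_echo": self.config_echo,
            "flags": self.flags,
        }

    def write(self, out_dir: PathLike) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        pd.DataFrame(
            self.candidates,
            columns=["drug", "mean", "enrichment", "n_instances", "targets"],
        ).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)


def run_pipeline(
    fixture_dir: PathLike,
    out_dir: Optional[PathLike] = None,
    policy: Policy = Policy.STRICT,
    min_abs_mean: float = 0.0,
    min_sources: int = 1,
    anchors_pos: tuple[str, ...] = ANCHORS_POS,
    anchors_neg: tuple[str, ...] = ANCHORS_NEG,
    from_stage: Optional[str] = None,
) -> PipelineReport:
    """Run the cascade over a fixture directory and return the report.

    ``from_stage="connectivity"`` resumes from a cached cascade (written by a
    previous full run into ``out_dir/cache``), skipping evidence ingestion
    and the pharmacological filters; with deterministic inputs the resumed
    report is identical to the full run's.
    """
    fixture_dir = Path(fixture_dir)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    cache_path = out_path / "cache" / "cascade.json" if out_path else None
    report = PipelineReport(
        config_echo={
            "fixture_dir": str(fixture_dir),
            "policy": policy.value,
            "min_abs_mean": min_abs_mean,
            "min_sources": min_sources,
            "anchors_pos": list(anchors_pos),
            "anchors_neg": list(anchors_neg),
            "from_stage": from_stage,
        }
    )
    if from_stage is not None and from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; expected one of {STAGES}")

    survivors: list[str]
    if from_stage == "connectivity":
        if cache_path is None or not cache_path.exists():
            raise FileNotFoundError(
                "resume from 'connectivity' requires a cached cascade under out_dir/cache"
            )
        with open(cache_path) as fh:
            cache = json.load(fh)
        report.stage_counts = [StageCount(**sc) for sc in cache["stage_counts"]]
        report.flags = cache["flags"]
        survivors = cache["survivors"]
        survivor_targets = {d: t for d, t in cache["survivor_targets"].items()}
    else:
        evid = fixture_dir / "evidence"
        for name, stage in (
            ("gwas.tsv", "ingest"), ("phewas.tsv", "ingest"),
            ("metabolites.tsv", "ingest"), ("transcriptome.txt", "ingest"),
            ("biomedical.txt", "ingest"),
        ):
            if not (evid / name).exists():
                raise FileNotFoundError(f"stage {stage}: missing input {evid / name}")
        records = []
        records += evidence_io.parse_gwas_evidence(evid / "gwas.tsv")
        records += evidence_io.parse_phewas_evidence(evid / "phewas.tsv")
        assocs, met_records = evidence_io.parse_metabolite_table(evid / "metabolites.tsv")
        records += met_records
        records += evidence_io.parse_gene_list(evid / "transcriptome.txt", Source.TRANSCRIPTOMICS)
        records += evidence_io.parse_gene_list(evid / "biomedical.txt", Source.BIOMEDICAL)
        report.stage_counts.append(StageCount("ingest", targets=len({r.gene for r in records})))
        if not records:
            report.flags.append("empty evidence: no records ingested")
            logger.warning("empty evidence: pipeline produced an empty report")
            if out_path:
                report.write(out_path)
            return report

        profiles = integration.build_profiles(records)
        gene_set = integration.unified_gene_set(profiles, min_sources=min_sources)
        counts = integration.venn_counts(profiles)
        report.stage_counts.append(StageCount("integrate", targets=len(gene_set)))
        report.config_echo["multi_source_total"] = integration.multi_source_total(counts)

        net = metnet.build_network(assocs)
        stats = metnet.network_stats(net)
        report.stage_counts.append(StageCount("metnet", targets=stats["n_proteins"]))
        report.config_echo["metnet_stats"] = stats

        ph = fixture_dir / "pharm"
        for name in ("drug_targets.tsv", "trials.tsv", "pathogenesis.tsv"):
            if not (ph / name).exists():
                raise FileNotFoundError(f"stage map: missing input {ph / name}")
        drug_targets = evidence_io.parse_drug_targets(ph / "drug_targets.tsv")
        candidates, n_mapped_targets = pharm.map_drugs(gene_set, drug_targets)
        report.stage_counts.append(
            StageCount("map", drugs=len(candidates), targets=n_mapped_targets)
        )

        trials = evidence_io.parse_trials(ph / "trials.tsv")
        retained, overlap = pharm.exclude_known(candidates, trials)
        report.stage_counts.append(
            StageCount(
                "exclude",
                drugs=len(retained),
                targets=len({t.target for c in retained for t in c.targets}),
            )
        )
        report.config_echo["trial_overlap"] = overlap
        if len(candidates) - overlap != len(retained):  # defensive; cannot happen
            report.flags.append("exclusion arithmetic inconsistent")

        annotations = evidence_io.parse_pathogenesis(ph / "pathogenesis.tsv")
        surviving = pharm.pathogenesis_filter(retained, annotations, policy=policy)
        surv_targets = pharm.surviving_targets(surviving, annotations)
        report.stage_counts.append(
            StageCount("pathofilter", drugs=len(surviving), targets=len(surv_targets))
        )
        if out_path:
            pharm.write_trace(candidates, out_path / "filter_trace.tsv")
        survivors = [c.drug for c in surviving]
        survivor_targets = {
            c.drug: sorted(t.target for t in c.targets) for c in surviving
        }
        if cache_path:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            with open(cache_path, "w") as fh:
                json.dump(
                    {
                        "stage_counts": [
                            {"stage": s.stage, "drugs": s.drugs, "targets": s.targets}
                            for s in report.stage_counts
                        ],
                        "flags": report.flags,
                        "survivors": survivors,
                        "survivor_targets": survivor_targets,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )

    # --- connectivity + selection -------------------------------------------
    sig_dir = fixture_dir / "signatures"
    if not (sig_dir / "manifest.tsv").exists():
        raise FileNotFoundError(f"stage connectivity: missing input {sig_dir / 'manifest.tsv'}")
    panel = read_signature_panel(sig_dir / "manifest.tsv")
    tags: TagSet = read_tagset(sig_dir / "tags.gmt")
    scores = connectivity_scores(tags, panel)
    results = aggregate_drugs(scores, {s.instance_id: s.drug for s in panel})
    report.stage_counts.append(
        StageCount("connectivity", drugs=len({s.drug for s in panel} & set(survivors)))
    )
    selection = select_candidates(
        results,
        anchors_pos=anchors_pos,
        anchors_neg=anchors_neg,
        min_abs_mean=min_abs_mean,
        candidates=survivors,
    )
    if selection.not_in_cmap:
        report.flags.append(
            f"{len(selection.not_in_cmap)} candidate drugs NOT_IN_CMAP (no signature panel entry)"
        )
    final_targets = {
        t for r in selection.retained for t in survivor_targets.get(r.drug, [])
    }
    report.stage_counts.append(
        StageCount("select", drugs=len(selection.retained), targets=len(final_targets))
    )
    report.candidates = [
        {
            "drug": r.drug,
            "mean": round(r.mean, 6),
            "enrichment": round(r.enrichment, 6),
            "n_instances": r.n_instances,
            "targets": ";".join(survivor_targets.get(r.drug, [])),
        }
        for r in selection.retained
    ]
    if out_path:
        decisions = {r.drug: "RETAINED" for r in selection.retained}
        decisions.update({r.drug: "REJECTED" for r in selection.rejected})
        decisions.update({d: "NOT_IN_CMAP" for d in selection.not_in_cmap})
        write_results(results, decisions, out_path / "connectivity.tsv")
        report.write(out_path)
    return report


# ---------------------------------------------------------------------------
# Published candidate-table checks
# ---------------------------------------------------------------------------

def packaged_table1_path() -> Path:
    return Path(importlib.resources.files("melanoseek") / "data" / "table1.tsv")


def table1_checks(fixture: Optional[PathLike] = None) -> dict:
    """Summary counts over the transcribed candidate-drug table.

    The table is exploded to one row per (drug, target) with the drug-level
    literature-evidence flag repeated.  Returns unique drug/target counts,
    evidence tallies, and per-policy concordance tallies over the rows.
    """
    path = Path(fixture) if fixture is not None else packaged_table1_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug", "target", "actions", "direction", "evidence"}
    if not required <= set(df.columns):
        raise evidence_io.FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    drugs = df["drug"].unique()
    evidence_by_drug = {
        d: (df.loc[df["drug"] == d, "evidence"].iloc[0].strip().lower() == "yes")
        for d in drugs
    }
    tally = {p.value: {v.value: 0 for v in Verdict} for p in Policy}
    for _, row in df.iterrows():
        direction = Direction(row["direction"].strip().upper())
        actions = frozenset(
            Action(a.strip().upper()) for a in row["actions"].split(";") if a.strip()
        )
        for p in Policy:
            best = min(
                (
                    pharm.concordance(direction, a, p, sibling_actions=actions)
                    for a in actions
                ),
                key=lambda v: [Verdict.CONCORDANT, Verdict.NEUTRAL, Verdict.DISCORDANT].index(v),
            )
            tally[p.value][best.value] += 1
    n_with = sum(1 for v in evidence_by_drug.values() if v)
    return {
        "n_drugs": len(drugs),
        "n_unique_targets": df["target"].str.strip().str.upper().nunique(),
        "n_with_evidence": n_with,
        "n_without_evidence": len(drugs) - n_with,
        "n_drug_target_pairs": len(df),
        "concordance_tally": tally,
    }
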