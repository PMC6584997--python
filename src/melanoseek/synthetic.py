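"""Synthetic fixture generator with planted, recoverable ground truth.

Every pipeline stage is testable offline: this module fabricates the five
evidence tables, the metabolite-protein table, the DrugBank-style drug-target
table, the trial list, the pathogenesis annotations and a panel of ranked
expression signatures, all with a known planted structure (per-source gene
counts, multi-source overlap, cascade survivor counts, connectivity-active
drugs).  The defaults reproduce the study conditions of the melanoma
repurposing cascade: 55/260/616/27/11 genes per source with 50 multi-source
genes, 23 metabolites with ~800 associations, a 731-drug/193-target mapping,
75 trial-overlapping drugs, 277 drugs on 74 annotated targets surviving the
concordance filter, and 35 connectivity-concordant finalists.

A single integer seed drives one named pseudo-random stream per file type
(stream-splitting by label), so adding a generator never perturbs existing
fixtures.  Regeneration under an identical (config, seed) is byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import evidence_io
from .connectivity import RankedSignature, TagSet, write_gmt, write_manifest, write_rnk
from .types import (
    Action,
    Direction,
    DrugGroup,
    DrugTargetRecord,
    LOWERING_ACTIONS,
    MetaboliteAssociation,
    PathogenesisAnnotation,
    RAISING_ACTIONS,
    Role,
    Source,
    TargetCategory,
    TrialRecord,
)

PathLike = Union[str, Path]


class SyntheticConfigError(ValueError):
    """Infeasible or invalid generator configuration."""


DEFAULT_SOURCE_SIZES = {
    Source.GWAS: 55,
    Source.PHEWAS: 260,
    Source.METABOLOMICS: 616,
    Source.TRANSCRIPTOMICS: 27,
    Source.BIOMEDICAL: 11,
}

# Multi-source genes called out by name in the melanoma literature, with the
# source combinations they were observed in; used first when planting overlap.
NAMED_OVERLAP = (
    ("TYR", (Source.PHEWAS, Source.GWAS, Source.BIOMEDICAL)),
    ("TERT", (Source.GWAS, Source.BIOMEDICAL)),
    ("CYP1B1", (Source.METABOLOMICS, Source.GWAS)),
    ("CYP19A1", (Source.METABOLOMICS, Source.PHEWAS)),
    ("CYP1A1", (Source.METABOLOMICS, Source.PHEWAS)),
)

ANCHORS_POS = ("paclitaxel", "vinblastine")
ANCHORS_NEG = ("selegiline",)

INDICATIONS = (
    "Hypertension", "Congestive heart failure", "Type 2 diabetes mellitus",
    "Respiratory tract infections", "Depression", "Peptic ulcer disease",
    "Rheumatoid arthritis", "Chronic asthma", "Tuberculosis", "Anxiety disorders",
)

CELL_LINES = ("MCF7", "PC3", "HL60", "SKMEL5")


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    source_sizes: dict[Source, int] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_SIZES)
    )
    multi_source_overlap: int = 50
    n_metabolites: int = 23
    n_assocs: int = 800
    gwas_p_range: tuple[float, float] = (4e-37, 8e-06)
    phewas_p_range: tuple[float, float] = (1.106e-16, 0.05)
    n_phewas_rows: int = 765  # SNP-level rows collapsing onto the PheWAS genes
    n_gwas_decoy_rows: int = 20
    n_phewas_decoy_rows: int = 40
    # pharm cascade plants
    n_mapped_targets: int = 193
    n_mapped_drugs: int = 731
    trial_overlap: int = 75
    n_trial_drugs: int = 215
    n_survivor_drugs: int = 277
    n_annotated_targets: int = 74
    n_nonapproved_decoys: int = 80
    n_outofset_decoys: int = 100
    # connectivity plants
    n_cmap_active: int = 35
    n_cmap_missing: int = 27
    n_cmap_inactive: int = 0
    instances_per_drug: int = 4
    signature_universe: int = 1000
    n_up_tags: int = 50
    n_down_tags: int = 50
    concentration: float = 0.02

    def validate(self) -> None:
        counts = {
            "multi_source_overlap": self.multi_source_overlap,
            "n_metabolites": self.n_metabolites,
            "n_assocs": self.n_assocs,
            **{f"source_sizes[{s.value}]": v for s, v in self.source_sizes.items()},
            "n_mapped_targets": self.n_mapped_targets,
            "n_mapped_drugs": self.n_mapped_drugs,
            "trial_overlap": self.trial_overlap,
            "n_survivor_drugs": self.n_survivor_drugs,
            "n_annotated_targets": self.n_annotated_targets,
        }
        for name, v in counts.items():
            if v < 0:
                raise SyntheticConfigError(f"{name} must be non-negative, got {v}")
        if self.concentration <= 0:
            raise SyntheticConfigError(
                f"concentration must be > 0, got {self.concentration}"
            )
        sizes = sorted(self.source_sizes.values(), reverse=True)
        if len(sizes) >= 2 and self.multi_source_overlap > sizes[0] + sizes[1]:
            raise SyntheticConfigError("multi_source_overlap exceeds feasible capacity")
        if self.n_survivor_drugs + self.trial_overlap > self.n_mapped_drugs:
            raise SyntheticConfigError("survivors + trial overlap exceed mapped drugs")
        if self.n_annotated_targets > self.n_mapped_targets:
            raise SyntheticConfigError("annotated targets exceed mapped targets")
        if self.n_annotated_targets > self.n_survivor_drugs and self.n_survivor_drugs > 0:
            raise SyntheticConfigError("cannot cover annotated targets with survivors")
        if self.n_cmap_active + self.n_cmap_missing + self.n_cmap_inactive > self.n_survivor_drugs:
            raise SyntheticConfigError("cmap panel plants exceed surviving drugs")
        if self.n_metabolites > 0 and self.n_assocs < max(
            self.source_sizes.get(Source.METABOLOMICS, 0), self.n_metabolites
        ):
            raise SyntheticConfigError("n_assocs too small to cover metabolites/proteins")


def _rng(seed: int, label: str) -> np.random.Generator:
    """One named, seed-stable pseudo-random stream per fixture type."""
    label_key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, label_key]))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

_SINGLETON_PREFIX = {
    Source.GWAS: "GWG",
    Source.PHEWAS: "PWG",
    Source.METABOLOMICS: "MPR",
    Source.TRANSCRIPTOMICS: "DEG",
    Source.BIOMEDICAL: "BMG",
}


def plan_gene_memberships(config: SyntheticConfig) -> dict[str, frozenset[Source]]:
    """Assign every synthetic gene its set of evidence sources.

    Exactly ``multi_source_overlap`` genes receive two or more sources (named
    literature genes first, then synthetic two-source genes placed into the
    sources with most remaining capacity); all remaining per-source quota is
    filled with source-unique singleton genes.
    """
    quotas = {s: int(n) for s, n in config.source_sizes.items()}
    memberships: dict[str, frozenset[Source]] = {}
    remaining = config.multi_source_overlap

    for gene, combo in NAMED_OVERLAP:
        if remaining == 0:
            break
        if all(quotas.get(s, 0) >= 1 for s in combo):
            memberships[gene] = frozenset(combo)
            for s in combo:
                quotas[s] -= 1
            remaining -= 1

    i = 0
    while remaining > 0:
        open_sources = sorted(
            (s for s, q in quotas.items() if q >= 1),
            key=lambda s: (-quotas[s], s.value),
        )
        if len(open_sources) < 2:
            raise SyntheticConfigError(
                "multi_source_overlap infeasible for the given source sizes"
            )
        combo = frozenset(open_sources[:2])
        memberships[f"OVL{i:04d}"] = combo
        for s in combo:
            quotas[s] -= 1
        remaining -= 1
        i += 1

    for source, quota in sorted(quotas.items(), key=lambda kv: kv[0].value):
        prefix = _SINGLETON_PREFIX[source]
        for j in range(quota):
            memberships[f"{prefix}{j:04d}"] = frozenset({source})
    return memberships


def generate_evidence(config: SyntheticConfig, out_dir: PathLike) -> dict:
    """Write the five evidence files; return the ground-truth manifest section."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    memberships = plan_gene_memberships(config)
    per_source: dict[Source, list[str]] = {s: [] for s in config.source_sizes}
    for gene in sorted(memberships):
        for s in memberships[gene]:
            per_source[s].append(gene)
    for s, size in config.source_sizes.items():
        assert len(per_source[s]) == size, (s, len(per_source[s]), size)

    # --- GWAS table: one row per gene plus endpoint rows and decoys ---------
    rng = _rng(config.seed, "gwas")
    gwas_genes = per_source.get(Source.GWAS, [])
    rows = []
    ps = _log_uniform(rng, *config.gwas_p_range, size=len(gwas_genes))
    if len(gwas_genes) >= 2:  # plant the exact reported p-value endpoints
        ps[0], ps[-1] = config.gwas_p_range[0], config.gwas_p_range[1]
    traits = ("Melanoma", "Cutaneous malignant melanoma")
    for i, gene in enumerate(gwas_genes):
        rows.append(
            {
                "disease/trait": traits[int(rng.integers(2))],
                "mapped_gene": gene,
                "snps": f"rs{int(rng.integers(10**6, 10**7))}",
                "p-value": f"{ps[i]:.3E}",
                "ancestry": "European",
                "pubmed_id": str(int(rng.integers(20_000_000, 30_000_000))),
            }
        )
    # intergenic two-gene cells exercising the explode rule (genes repeat, so
    # per-source unique counts are unchanged)
    if len(gwas_genes) >= 4:
        for g1, g2 in [(gwas_genes[0], gwas_genes[1]), (gwas_genes[2], gwas_genes[3])]:
            rows.append(
                {
                    "disease/trait": "Melanoma",
                    "mapped_gene": f"{g1} - {g2}",
                    "snps": f"rs{int(rng.integers(10**6, 10**7))}",
                    "p-value": f"{_log_uniform(rng, *config.gwas_p_range, 1)[0]:.3E}",
                    "ancestry": "East Asian",
                    "pubmed_id": str(int(rng.integers(20_000_000, 30_000_000))),
                }
            )
    for _ in range(config.n_gwas_decoy_rows):  # wrong-trait rows must be filtered out
        rows.append(
            {
                "disease/trait": str(rng.choice(["Lung cancer", "Height", "Psoriasis"])),
                "mapped_gene": f"DCY{int(rng.integers(1000)):04d}",
                "snps": f"rs{int(rng.integers(10**6, 10**7))}",
                "p-value": f"{_log_uniform(rng, 1e-20, 1e-6, 1)[0]:.3E}",
                "ancestry": "European",
                "pubmed_id": str(int(rng.integers(20_000_000, 30_000_000))),
            }
        )
    order = rng.permutation(len(rows))
    import pandas as pd

    pd.DataFrame([rows[i] for i in order]).to_csv(out_dir / "gwas.tsv", sep="\t", index=False)

    # --- PheWAS table: n_phewas_rows SNP rows over the PheWAS genes ---------
    rng = _rng(config.seed, "phewas")
    phewas_genes = per_source.get(Source.PHEWAS, [])
    rows = []
    n_rows = max(config.n_phewas_rows, len(phewas_genes))
    if phewas_genes:
        gene_of_row = list(phewas_genes) + [
            phewas_genes[int(rng.integers(len(phewas_genes)))]
            for _ in range(n_rows - len(phewas_genes))
        ]
        ps = _log_uniform(rng, *config.phewas_p_range, size=n_rows)
        if n_rows >= 2:
            ps[0], ps[-1] = config.phewas_p_range[0], config.phewas_p_range[1]
        phenos = ("Melanoma", "Skin cancer")
        for i, gene in enumerate(gene_of_row):
            rows.append(
                {
                    "phewas phenotype": phenos[int(rng.integers(2))],
                    "snp": f"rs{int(rng.integers(10**6, 10**7))}",
                    "p-value": f"{ps[i]:.4E}",
                    "gene_name": gene,
                }
            )
    for _ in range(config.n_phewas_decoy_rows):
        # decoys: either a non-significant p-value or an unrelated phenotype
        if rng.random() < 0.5:
            rows.append(
                {
                    "phewas phenotype": "Melanoma",
                    "snp": f"rs{int(rng.integers(10**6, 10**7))}",
                    "p-value": f"{rng.uniform(0.051, 0.9):.4f}",
                    "gene_name": f"DCY{int(rng.integers(1000)):04d}",
                }
            )
        else:
            rows.append(
                {
                    "phewas phenotype": "Gout",
                    "snp": f"rs{int(rng.integers(10**6, 10**7))}",
                    "p-value": f"{rng.uniform(1e-6, 0.05):.4E}",
                    "gene_name": f"DCY{int(rng.integers(1000)):04d}",
                }
            )
    order = rng.permutation(len(rows))
    pd.DataFrame([rows[i] for i in order]).to_csv(
        out_dir / "phewas.tsv", sep="\t", index=False
    )

    # --- metabolite-protein table -------------------------------------------
    rng = _rng(config.seed, "metabolites")
    proteins = per_source.get(Source.METABOLOMICS, [])
    metabolites = [f"Metabolite_{i + 1:02d}" for i in range(config.n_metabolites)]
    pairs: set[tuple[str, str]] = set()
    assoc_rows = []
    roles = [Role.ENZYME, Role.TRANSPORTER, Role.UNKNOWN]
    role_p = [0.5, 0.3, 0.2]
    if metabolites and proteins:
        for i, prot in enumerate(proteins):  # cover every protein
            met = metabolites[i % len(metabolites)] if i < len(metabolites) else (
                metabolites[int(rng.integers(len(metabolites)))]
            )
            pairs.add((met, prot))
        while len(pairs) < config.n_assocs:
            pairs.add(
                (
                    metabolites[int(rng.integers(len(metabolites)))],
                    proteins[int(rng.integers(len(proteins)))],
                )
            )
        for met, prot in sorted(pairs):
            assoc_rows.append(
                {
                    "metabolite": met,
                    "protein": prot,
                    "role": roles[int(rng.choice(3, p=role_p))].value,
                }
            )
    order = rng.permutation(len(assoc_rows)) if assoc_rows else []
    pd.DataFrame(
        [assoc_rows[i] for i in order], columns=["metabolite", "protein", "role"]
    ).to_csv(out_dir / "metabolites.tsv", sep="\t", index=False)

    # --- plain gene lists ----------------------------------------------------
    (out_dir / "transcriptome.txt").write_text(
        "".join(g + "\n" for g in per_source.get(Source.TRANSCRIPTOMICS, []))
    )
    (out_dir / "biomedical.txt").write_text(
        "".join(g + "\n" for g in per_source.get(Source.BIOMEDICAL, []))
    )

    union = sorted(memberships)
    multi = sum(1 for combo in memberships.values() if len(combo) >= 2)
    return {
        "source_sizes": {s.value: len(g) for s, g in per_source.items()},
        "union_size": len(union),
        "multi_source_total": multi,
        "union": union,
        "per_source": {s.value: sorted(g) for s, g in per_source.items()},
        "n_metabolites": len(metabolites) if proteins else 0,
        "n_metabolite_proteins": len(proteins),
        "n_assocs": len(pairs),
    }


# ---------------------------------------------------------------------------
# Pharm cascade
# ---------------------------------------------------------------------------

def generate_pharm(config: SyntheticConfig, evidence_truth: dict, out_dir: PathLike) -> dict:
    """Write drug-target, trial and pathogenesis tables with a planted cascade.

    When the cascade runs with the STRICT policy the planted counts are
    recovered exactly: ``n_mapped_drugs`` drugs on ``n_mapped_targets``
    targets, ``trial_overlap`` drugs excluded as known-indication, and
    ``n_survivor_drugs`` drugs on ``n_annotated_targets`` annotated targets
    surviving concordance filtering.  Decoys (non-approved drugs, drugs on
    out-of-set targets) are interleaved.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, "pharm")
    union: list[str] = list(evidence_truth["union"])
    if config.n_mapped_targets > len(union):
        raise SyntheticConfigError("n_mapped_targets exceeds the evidence union size")

    targets = [union[i] for i in rng.choice(len(union), config.n_mapped_targets, replace=False)]
    annotated = targets[: config.n_annotated_targets]
    unannotated = targets[config.n_annotated_targets:]

    directions = {
        t: (Direction.GOF if i % 2 == 0 else Direction.LOF)
        for i, t in enumerate(annotated)
    }

    n_drugs = config.n_mapped_drugs
    names = [f"Drug{i + 1:04d}" for i in range(n_drugs)]
    shuffled = [names[i] for i in rng.permutation(n_drugs)]
    survivors = shuffled[: config.n_survivor_drugs]
    trial_drugs = shuffled[config.n_survivor_drugs: config.n_survivor_drugs + config.trial_overlap]
    failers = shuffled[config.n_survivor_drugs + config.trial_overlap:]

    concordant_of = {
        Direction.GOF: sorted(a.value for a in LOWERING_ACTIONS),
        Direction.LOF: sorted(a.value for a in RAISING_ACTIONS),
    }
    discordant_of = {
        Direction.GOF: sorted(a.value for a in RAISING_ACTIONS),
        Direction.LOF: sorted(a.value for a in LOWERING_ACTIONS),
    }
    categories = [TargetCategory.PROTEIN, TargetCategory.ENZYME, TargetCategory.TRANSPORTER]

    records: list[DrugTargetRecord] = []
    drug_id_of = {name: f"SB{i + 1:05d}" for i, name in enumerate(names)}

    def add(drug: str, target: str, actions: frozenset[Action], group=DrugGroup.APPROVED) -> None:
        records.append(
            DrugTargetRecord(
                drug=drug,
                drug_id=drug_id_of.get(drug, f"SB9{abs(zlib.crc32(drug.encode())) % 10**4:04d}"),
                group=group,
                target=target,
                target_category=categories[int(rng.integers(3))],
                actions=actions,
                indication=str(rng.choice(INDICATIONS)),
            )
        )

    # survivors: each carries one annotated target with a concordant (or, for
    # a few, neutral substrate) action; annotated targets are covered i % k
    for i, drug in enumerate(survivors):
        if not annotated:
            break
        target = annotated[i % len(annotated)]
        pool = concordant_of[directions[target]]
        if i % 9 == 8 and i >= len(annotated):
            actions = frozenset({Action.SUBSTRATE})  # neutral: still retained
        else:
            actions = frozenset({Action(str(rng.choice(pool)))})
        add(drug, target, actions)
        if i % 7 == 3 and unannotated:  # occasional second, unannotated target
            add(drug, unannotated[int(rng.integers(len(unannotated)))],
                frozenset({Action.SUBSTRATE}))

    # trial-overlap drugs: any mapped target, any action; removed pre-concordance
    for i, drug in enumerate(trial_drugs):
        target = targets[int(rng.integers(len(targets)))]
        add(drug, target, frozenset({list(Action)[int(rng.integers(len(Action)))]}))

    # failers: first cover every unannotated target (NO_ANNOTATION rejects),
    # then alternate unannotated targets and discordant annotated targets
    for i, drug in enumerate(failers):
        if i < len(unannotated):
            add(drug, unannotated[i], frozenset({list(Action)[int(rng.integers(len(Action)))]}))
        elif i % 2 == 0 and unannotated:
            add(drug, unannotated[int(rng.integers(len(unannotated)))],
                frozenset({list(Action)[int(rng.integers(len(Action)))]}))
        elif annotated:
            target = annotated[int(rng.integers(len(annotated)))]
            pool = discordant_of[directions[target]]
            add(drug, target, frozenset({Action(str(rng.choice(pool)))}))
        else:
            add(drug, unannotated[i % len(unannotated)],
                frozenset({list(Action)[int(rng.integers(len(Action)))]}))

    # decoys: wrong approval group on in-set targets; approved on out-of-set genes
    nonapproved_groups = [
        DrugGroup.EXPERIMENTAL, DrugGroup.ILLICIT, DrugGroup.WITHDRAWN,
        DrugGroup.INVESTIGATIONAL, DrugGroup.NUTRACEUTICAL,
    ]
    for i in range(config.n_nonapproved_decoys):
        add(
            f"NonApproved{i + 1:03d}",
            targets[int(rng.integers(len(targets)))] if targets else f"OFF{i:04d}",
            frozenset({list(Action)[int(rng.integers(len(Action)))]}),
            group=nonapproved_groups[i % len(nonapproved_groups)],
        )
    for i in range(config.n_outofset_decoys):
        add(
            f"OffTarget{i + 1:03d}",
            f"OFF{i:04d}",
            frozenset({list(Action)[int(rng.integers(len(Action)))]}),
        )

    order = rng.permutation(len(records))
    evidence_io.write_drug_targets([records[i] for i in order], out_dir / "drug_targets.tsv")

    # trial list: the overlap drugs under name variants + filler + anchors
    stages = ("Phase 1", "Phase 2", "Phase 3", "Phase 4", "Phase 0")
    statuses = ("completed", "recruiting", "suspended", "terminated")
    trials: list[TrialRecord] = []
    for i, drug in enumerate(trial_drugs):
        variant = drug.lower() if i % 2 == 0 else drug.upper().replace("DRUG", "DRUG-")
        trials.append(
            TrialRecord(
                drug=variant,
                stage=f"{stages[i % len(stages)]} ({statuses[i % len(statuses)]})",
                condition="Melanoma",
            )
        )
    n_filler = max(0, config.n_trial_drugs - len(trial_drugs) - len(ANCHORS_POS) - len(ANCHORS_NEG))
    for anchor in ANCHORS_POS + ANCHORS_NEG:
        trials.append(TrialRecord(drug=anchor, stage="Phase 4", condition="Melanoma"))
    for i in range(n_filler):
        trials.append(
            TrialRecord(
                drug=f"TrialOnly{i + 1:03d}",
                stage=stages[i % len(stages)],
                condition="Melanoma",
            )
        )
    evidence_io.write_trials(trials, out_dir / "trials.tsv")

    annotations = [
        PathogenesisAnnotation(
            target=t,
            direction=directions[t],
            description="synthetic pathogenic role",
            provenance="OMIM-like flag (synthetic)",
        )
        for t in annotated
    ]
    evidence_io.write_pathogenesis(annotations, out_dir / "pathogenesis.tsv")

    return {
        "mapped_targets": len(set(targets)),
        "mapped_drugs": n_drugs,
        "trial_overlap": len(trial_drugs),
        "retained_after_exclusion": n_drugs - len(trial_drugs),
        "survivor_drugs": len(survivors),
        "annotated_targets": len(annotated),
        "survivors": sorted(survivors),
        "n_trial_records": len(trials),
    }


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

def _biased_permutation(
    rng: np.random.Generator,
    universe: list[str],
    top_tags: list[str],
    bottom_tags: list[str],
    concentration: float,
) -> tuple[str, ...]:
    """Permutation with ``top_tags`` geometrically biased toward position 1
    and ``bottom_tags`` toward position n (truncated-geometric offsets)."""
    n = len(universe)
    taken: set[int] = set()
    placed: dict[int, str] = {}
    p = 1.0 - float(np.exp(-concentration))

    def place(gene: str, from_top: bool) -> None:
        for _ in range(64):
            off = int(rng.geometric(p)) - 1
            if off < n:
                idx = off if from_top else n - 1 - off
                if idx not in taken:
                    taken.add(idx)
                    placed[idx] = gene
                    return
        # fall back to the first free slot scanning from the biased end
        scan = range(n) if from_top else range(n - 1, -1, -1)
        for idx in scan:
            if idx not in taken:
                taken.add(idx)
                placed[idx] = gene
                return

    for gene in top_tags:
        place(gene, from_top=True)
    for gene in bottom_tags:
        place(gene, from_top=False)
    tagged = set(top_tags) | set(bottom_tags)
    rest = [g for g in universe if g not in tagged]
    rest = [rest[i] for i in rng.permutation(len(rest))]
    free = [i for i in range(n) if i not in taken]
    for idx, gene in zip(free, rest):
        placed[idx] = gene
    return tuple(placed[i] for i in range(n))


def generate_signatures(
    config: SyntheticConfig,
    drug_panel: Optional[list[str]] = None,
    tags: Optional[TagSet] = None,
) -> tuple[list[RankedSignature], TagSet, dict]:
    """Build the ranked-signature panel with planted actives and reversed drugs.

    ``drug_panel`` is the pool of candidate drugs reaching the connectivity
    stage (defaults to the planted cascade survivors).  Within it,
    ``n_cmap_active`` drugs mimic the disease query (up-tags near the top,
    down-tags near the bottom), ``n_cmap_inactive`` get uniform permutations,
    ``n_cmap_missing`` are left out of the panel entirely, and the remainder
    are reversed.  The positive anchor drugs are planted active and the
    negative anchor reversed.
    """
    config.validate()
    rng = _rng(config.seed, "signatures")
    if drug_panel is None:
        drug_panel = [f"Drug{i + 1:04d}" for i in range(config.n_survivor_drugs)]
    drug_panel = sorted(drug_panel)
    if config.n_cmap_active + config.n_cmap_missing + config.n_cmap_inactive > len(drug_panel):
        raise SyntheticConfigError("cmap plants exceed the drug panel size")

    universe = [f"SIG_G{i:04d}" for i in range(config.signature_universe)]
    if tags is None:
        if config.n_up_tags + config.n_down_tags > len(universe):
            raise SyntheticConfigError("tag sets exceed the signature universe")
        picks = rng.choice(len(universe), config.n_up_tags + config.n_down_tags, replace=False)
        tags = TagSet(
            up=frozenset(universe[i] for i in picks[: config.n_up_tags]),
            down=frozenset(universe[i] for i in picks[config.n_up_tags:]),
        )
    missing_tags = (tags.up | tags.down) - set(universe)
    if missing_tags:
        raise SyntheticConfigError(
            f"tag genes outside the signature universe: {sorted(missing_tags)[:3]}"
        )

    idx = rng.permutation(len(drug_panel))
    active = sorted(drug_panel[i] for i in idx[: config.n_cmap_active])
    pos = config.n_cmap_active
    missing = sorted(drug_panel[i] for i in idx[pos: pos + config.n_cmap_missing])
    pos += config.n_cmap_missing
    inactive = sorted(drug_panel[i] for i in idx[pos: pos + config.n_cmap_inactive])
    pos += config.n_cmap_inactive
    reversed_drugs = sorted(drug_panel[i] for i in idx[pos:])

    up_list, down_list = sorted(tags.up), sorted(tags.down)
    signatures: list[RankedSignature] = []

    def emit(drug: str, kind: str) -> None:
        for k in range(config.instances_per_drug):
            if kind == "active":
                ranking = _biased_permutation(rng, universe, up_list, down_list, config.concentration)
            elif kind == "reversed":
                ranking = _biased_permutation(rng, universe, down_list, up_list, config.concentration)
            else:
                ranking = tuple(universe[i] for i in rng.permutation(len(universe)))
            signatures.append(
                RankedSignature(
                    instance_id=f"{drug}__{k + 1}",
                    drug=drug,
                    cell_line=CELL_LINES[k % len(CELL_LINES)],
                    ranking=ranking,
                )
            )

    for drug in active:
        emit(drug, "active")
    for drug in inactive:
        emit(drug, "inactive")
    for drug in reversed_drugs:
        emit(drug, "reversed")
    for drug in ANCHORS_POS:
        emit(drug, "active")
    for drug in ANCHORS_NEG:
        emit(drug, "reversed")

    truth = {
        "active": active,
        "reversed": reversed_drugs,
        "inactive": inactive,
        "not_in_cmap": missing,
        "anchors_pos": list(ANCHORS_POS),
        "anchors_neg": list(ANCHORS_NEG),
        "n_final_expected": len(active),
        "n_instances": len(signatures),
        "universe_size": len(universe),
    }
    return signatures, tags, truth


def write_signature_fixtures(
    signatures: list[RankedSignature], tags: TagSet, out_dir: PathLike
) -> None:
    """Write RNK files, the instance manifest and the GMT tag sets."""
    out_dir = Path(out_dir)
    rnk_dir = out_dir / "rnk"
    rnk_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sig in signatures:
        fname = f"rnk/{sig.instance_id}.rnk"
        write_rnk(sig, out_dir / fname)
        paths[sig.instance_id] = fname
    write_manifest(signatures, paths, out_dir / "manifest.tsv")
    write_gmt({"up": tags.up, "down": tags.down}, out_dir / "tags.gmt", "disease query")


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def generate_all(
    config: SyntheticConfig, out_dir: PathLike, write_signatures: bool = True
) -> dict:
    """Generate the complete fixture tree plus ``truth.json``; return the truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    evidence_truth = generate_evidence(config, out_dir / "evidence")
    pharm_truth = generate_pharm(config, evidence_truth, out_dir / "pharm")
    signatures, tags, sig_truth = generate_signatures(
        config, drug_panel=pharm_truth["survivors"]
    )
    if write_signatures:
        write_signature_fixtures(signatures, tags, out_dir / "signatures")
    truth = {
        "seed": config.seed,
        "evidence": {k: v for k, v in evidence_truth.items() if k not in ("union", "per_source")},
        "pharm": {k: v for k, v in pharm_truth.items() if k != "survivors"},
        "cmap": {k: v for k, v in sig_truth.items() if k not in ("reversed",)},
        "cmap_reversed_count": len(sig_truth["reversed"]),
        "stage_counts": {
            "ingest_genes": evidence_truth["union_size"],
            "multi_source_total": evidence_truth["multi_source_total"],
            "map": {
                "drugs": pharm_truth["mapped_drugs"],
                "targets": pharm_truth["mapped_targets"],
            },
            "exclude": {
                "drugs": pharm_truth["retained_after_exclusion"],
                "overlap": pharm_truth["trial_overlap"],
            },
            "pathofilter": {
                "drugs": pharm_truth["survivor_drugs"],
                "targets": pharm_truth["annotated_targets"],
            },
            "select": {"drugs": sig_truth["n_final_expected"]},
        },
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    # full detail (gene lists, drug categories) for recovery tests
    with open(out_dir / "truth_detail.json", "w") as fh:
        json.dump(
            {
                "per_source": evidence_truth["per_source"],
                "union": evidence_truth["union"],
                "survivors": pharm_truth["survivors"],
                "cmap": sig_truth,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return truth
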