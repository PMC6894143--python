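"""Synthetic toy genomes, ontologies, regulatory resource bundles, and
patient cohorts with planted driver genes.

The generator emits every file format the readers consume (OBO ontology,
gene/expression/DE TSVs, TAD and enhancer BEDs, binned Hi-C triplets,
PCHiC/DHS BEDPEs, patient SV BEDPEs and HPO profiles) plus a ground-truth
table stating, per patient, the planted driver gene, its mechanism and the
expected driver tier. Everything is reproducible: the same seed yields
byte-identical files.

Planting logic, in brief: the ontology is split into "phenotype" branches
(patient profiles are drawn here) and "background" branches (decoy gene
annotations live there, so decoy genes never phenomatch a patient). Rare
leaf terms annotated to a single background gene carry high information
content (IC ~ ln(2000) > 5), so sharing them between a patient profile and
the planted gene produces high phenomatches; common leaves (~tens of genes)
produce low phenomatches only. The annotation universe includes ~2000
background genes because a 60-gene toy locus alone could never reach the
"phenomatch score > 5" regime (max IC would be ln(60) ~ 4.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as svio
from .direct_effects import classify_direct_effect
from .model import (
    AnalysisConfig,
    BreakpointEnd,
    BreakpointJunction,
    GeneRecord,
    GenomicInterval,
    PhenotypeProfile,
    SVSet,
)
from .ontology import Ontology
from .position_effects import evaluate_position_effect

MODES = ("direct_del", "direct_trunc", "direct_dup", "position_enhancer_loss", "none")
ASSOCIATION_LEVELS = ("none", "weak", "medium", "strong")

# expected tier from (association level, planted SV-effect strength),
# coded independently of classify.classify_tier
_EXPECTED_TIER = {
    ("strong", "strong"): "T1",
    ("medium", "strong"): "T2",
    ("weak", "strong"): "T2",
    ("strong", "weak"): "T2",
    ("medium", "weak"): "T2",
    ("weak", "weak"): "T3",
}

_DEFAULT_DRIVER_CYCLE = [
    ("direct_del", "strong"),
    ("direct_trunc", "strong"),
    ("position_enhancer_loss", "strong"),
    ("direct_dup", "medium"),
    ("direct_del", "medium"),
    ("position_enhancer_loss", "medium"),
    ("direct_trunc", "weak"),
    ("none", "none"),
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    n_genes: int = 60
    n_cell_types: int = 3
    hic_resolution_bp: int = 40_000
    tad_size_range: tuple[int, int] = (600_000, 1_200_000)
    n_hpo_terms: int = 150
    ontology_depth: int = 3
    n_patients: int = 8
    n_background_genes: int = 2000
    patient_n_terms: int = 8
    decoys_per_patient: int = 2
    hic_base: float = 1.0
    intra_tad_boost: float = 5.0
    enhancer_cluster_size: int = 5
    # explicit (mode, association) plan per patient; default cycle when None
    drivers: Optional[list[tuple[str, str]]] = None

    def driver_plan(self) -> list[tuple[str, str]]:
        plan = self.drivers or [
            _DEFAULT_DRIVER_CYCLE[i % len(_DEFAULT_DRIVER_CYCLE)]
            for i in range(self.n_patients)
        ]
        if len(plan) != self.n_patients:
            raise ValueError("driver plan length must equal n_patients")
        for mode, assoc in plan:
            if mode not in MODES or assoc not in ASSOCIATION_LEVELS:
                raise ValueError(f"invalid planted driver ({mode}, {assoc})")
            if mode == "none" and assoc != "none":
                raise ValueError("mode 'none' requires association 'none'")
            if mode != "none" and assoc == "none":
                raise ValueError("planted drivers need an association level")
            if mode == "direct_dup" and assoc != "medium":
                # a duplication's effect strength depends on its (data-driven)
                # support score; only medium association gives the same tier
                # (T2) for either outcome, keeping the ground truth exact
                raise ValueError("direct_dup plantings require medium association")
        return plan


@dataclass
class GroundTruthRow:
    patient_id: str
    mode: str
    association: str
    target_gene: str
    target_chrom: str
    expected_tier: str


@dataclass
class SimulatedCohort:
    out_dir: Path
    config: SimulationConfig
    resources_yaml: Path
    genes_tsv: Path
    gene2hpo_tsv: Path
    ontology_obo: Path
    ground_truth_tsv: Path
    patients: list[dict] = field(default_factory=list)  # id, svs, hpo, de paths
    ground_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def ensure_enhancer_bearing(
    enhancers_by_ct: dict[str, dict[str, list[tuple[int, int]]]],
    chrom: str,
    tad: tuple[int, int],
) -> None:
    """Refuse to plant an enhancer-loss driver in a TAD with no enhancers."""
    s, e = tad
    for ct, by_chrom in enhancers_by_ct.items():
        if not any(s < ee and ss < e for ss, ee in by_chrom.get(chrom, [])):
            raise ValueError(
                f"cannot plant enhancer-loss driver: TAD {chrom}:{s}-{e} "
                f"has no enhancers in cell type {ct}"
            )


# ---------------------------------------------------------------------------
# ontology construction
# ---------------------------------------------------------------------------

def simulate_ontology(
    n_rare_a: int,
    n_common_a: int,
    n_rare_b: int,
    n_common_b: int,
    depth: int,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, list[str], str]], dict[str, list[str]]]:
    """Build term stanzas (id, parents, name) and leaf pools.

    Returns (terms, pools) where pools maps rare_a/common_a/rare_b/common_b
    to leaf term id lists. depth=1 gives a star ontology (all leaves under
    the root, so distinct leaves share only the root ancestor).
    """
    terms: list[tuple[str, list[str], str]] = []
    counter = [1]

    def new_term(parents: list[str], name: str) -> str:
        tid = f"HP:{counter[0]:07d}"
        counter[0] += 1
        terms.append((tid, parents, name))
        return tid

    root = new_term([], "All")
    pools: dict[str, list[str]] = {
        k: [] for k in ("rare_a", "common_a", "rare_b", "common_b", "groups")
    }
    wanted = {"rare_a": n_rare_a, "common_a": n_common_a,
              "rare_b": n_rare_b, "common_b": n_common_b}

    if depth <= 1:
        for pool, n in wanted.items():
            for i in range(n):
                pools[pool].append(new_term([root], f"{pool} leaf {i}"))
        return terms, pools

    for pool, n in wanted.items():
        branch = new_term([root], f"{pool} branch")
        # chain of intermediate levels below the branch
        stem = branch
        for lvl in range(depth - 2):
            stem = new_term([stem], f"{pool} level {lvl + 2}")
        parents = [stem]
        leaves_per_parent = 5
        parent_nodes = [
            new_term(parents, f"{pool} group {g}")
            for g in range(max(1, -(-n // leaves_per_parent)))
        ]
        pools["groups"].extend(parent_nodes)
        for i in range(n):
            pools[pool].append(
                new_term([parent_nodes[i // leaves_per_parent]], f"{pool} leaf {i}")
            )
    return terms, pools


def write_obo(terms: list[tuple[str, list[str], str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy-hpo\n")
        for tid, parents, name in terms:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            for p in parents:
                fh.write(f"is_a: {p} ! parent\n")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig, out_dir) -> SimulatedCohort:
    """Generate a complete cohort with planted drivers under ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    (out / "patients").mkdir(parents=True, exist_ok=True)
    res = config.hic_resolution_bp
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chrom_length_bp for c in chroms}
    plan = config.driver_plan()
    patient_ids = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    # --- shared TAD scaffold, jittered per cell type -----------------------
    shared_tads: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        bounds = [0]
        while bounds[-1] < sizes[chrom]:
            size = int(rng.integers(*config.tad_size_range))
            bounds.append(min(sizes[chrom], bounds[-1] + (size // res) * res))
        shared_tads[chrom] = list(zip(bounds[:-1], bounds[1:]))

    cell_types = [f"CT{i + 1:02d}" for i in range(config.n_cell_types)]
    tads_by_ct: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ct in cell_types:
        tads_by_ct[ct] = {}
        for chrom in chroms:
            bounds = [s for s, _ in shared_tads[chrom]] + [sizes[chrom]]
            jit = list(bounds)
            for k in range(1, len(jit) - 1):
                jit[k] = bounds[k] + int(rng.integers(-1, 2)) * res
            tads_by_ct[ct][chrom] = list(zip(jit[:-1], jit[1:]))

    # --- genes: placed in the left half of each TAD's interior -------------
    margin = 3 * res
    genes: list[GeneRecord] = []
    gene_meta: dict[str, dict] = {}  # symbol -> {tad, chrom}
    slots = [(chrom, tad) for chrom in chroms for tad in shared_tads[chrom]]
    cursor: dict[tuple[str, tuple[int, int]], int] = {}
    gi = 0
    attempts = 0
    while gi < config.n_genes and attempts < 10 * config.n_genes:
        chrom, tad = slots[attempts % len(slots)]
        attempts += 1
        s, e = tad
        usable_end = s + margin + (e - s - 2 * margin) // 2
        pos = cursor.get((chrom, tad), s + margin)
        length = int(rng.integers(8_000, 40_000))
        start = pos + int(rng.integers(0, 10_000))
        if start + length > usable_end:
            continue
        cursor[(chrom, tad)] = start + length + 25_000
        symbol = f"GENE{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(
                symbol=symbol,
                refseq_id=f"NM_{100000 + gi}",
                interval=GenomicInterval(chrom, start, start + length, strand),
            )
        )
        gene_meta[symbol] = {"tad": tad, "chrom": chrom}
        gi += 1
    if gi < config.n_genes:
        raise ValueError("genome too small for the requested gene count")
    genes_by_chrom: dict[str, list[GeneRecord]] = {c: [] for c in chroms}
    for g in genes:
        genes_by_chrom[g.chrom].append(g)

    # --- assign target genes and TAD roles ---------------------------------
    tad_role: dict[tuple[str, tuple[int, int]], str] = {}
    targets: list[Optional[GeneRecord]] = []
    used: set[str] = set()
    for i, (mode, assoc) in enumerate(plan):
        if mode == "none":
            targets.append(None)
            continue
        chrom = chroms[i % len(chroms)]
        chosen = None
        for g in genes_by_chrom[chrom]:
            if g.symbol in used:
                continue
            tad = gene_meta[g.symbol]["tad"]
            key = (chrom, tad)
            if mode == "position_enhancer_loss":
                # needs free space for a cluster right of the gene
                if tad_role.get(key, "cluster") != "cluster":
                    continue
                # room for the cluster plus a junction window right of the gene
                if tad[1] - margin - 150_000 - 4 * res - 20_000 <= g.interval.end:
                    continue
                tad_role[key] = "cluster"
            elif mode == "direct_dup":
                if tad_role.get(key, "empty") != "empty":
                    continue
                if not (tad[0] + margin < g.interval.start - 25_000
                        and g.interval.end + 25_000 < tad[1] - margin):
                    continue
                tad_role[key] = "empty"
            chosen = g
            break
        if chosen is None:
            raise ValueError(f"no suitable target gene for patient {patient_ids[i]} ({mode})")
        used.add(chosen.symbol)
        targets.append(chosen)

    # --- ontology sized to the cohort's rare-term demand --------------------
    rare_need = sum(3 if a == "strong" else 1 for m, a in plan if m != "none")
    n_rare_a = max(10, rare_need + 5)
    n_common_a = max(20, config.n_hpo_terms // 5)
    terms, pools = simulate_ontology(
        n_rare_a, n_common_a, 10, max(20, config.n_hpo_terms // 5),
        config.ontology_depth, rng,
    )
    write_obo(terms, out / "ontology.obo")

    # --- annotations: background genes + planted driver terms ---------------
    gene2hpo: dict[str, set[str]] = {}
    rare_all = pools["rare_a"] + pools["rare_b"]
    for k, leaf in enumerate(rare_all):
        gene2hpo[f"BGG{k + 1:05d}"] = {leaf}  # one dedicated gene per rare leaf
    # keep intermediate nodes common (IC < high threshold) by annotating
    # background genes directly to them: only the planted leaf itself should
    # reach the high-phenomatch regime
    k = len(rare_all)
    for group in pools["groups"]:
        for _ in range(30):
            k += 1
            gene2hpo[f"BGG{k:05d}"] = {group}
    common_all = pools["common_a"] + pools["common_b"]
    for k in range(k, config.n_background_genes):
        n_ann = int(rng.integers(1, 4))
        picks = rng.choice(len(common_all), size=n_ann, replace=False)
        gene2hpo[f"BGG{k + 1:05d}"] = {common_all[p] for p in picks}

    rare_iter = iter(pools["rare_a"])
    profiles: list[Optional[PhenotypeProfile]] = []
    for i, (mode, assoc) in enumerate(plan):
        n_terms = config.patient_n_terms
        if mode != "none":
            target = targets[i]
            n_rare = 3 if assoc == "strong" else 1
            rare_terms = [next(rare_iter) for _ in range(n_rare)]
            common_pick = rng.choice(
                len(pools["common_a"]), size=n_terms - n_rare, replace=False
            )
            common_terms = [pools["common_a"][p] for p in common_pick]
            profile_terms = frozenset(rare_terms + common_terms)
            gene2hpo.setdefault(target.symbol, set()).update(rare_terms)
            gene2hpo[target.symbol].add(common_terms[0])
        else:
            common_pick = rng.choice(len(pools["common_a"]), size=n_terms, replace=False)
            profile_terms = frozenset(pools["common_a"][p] for p in common_pick)
        profiles.append(
            PhenotypeProfile(
                patient_id=patient_ids[i],
                hpo_terms=profile_terms,
                sex="male" if rng.random() < 0.5 else "female",
            )
        )

    # decoy / non-target genes: background-branch annotations only
    for g in genes:
        if g.symbol in used:
            continue
        if rng.random() < 0.5:
            picks = rng.choice(len(pools["common_b"]), size=int(rng.integers(1, 3)), replace=False)
            gene2hpo[g.symbol] = {pools["common_b"][p] for p in picks}

    with open(out / "gene2hpo.tsv", "w") as fh:
        fh.write("#symbol\thpo_id\n")
        for sym in sorted(gene2hpo):
            for t in sorted(gene2hpo[sym]):
                fh.write(f"{sym}\t{t}\n")

    # --- disease annotation of genes ----------------------------------------
    assoc_by_gene = {targets[i].symbol: plan[i][1] for i in range(len(plan)) if targets[i]}
    annotated: list[GeneRecord] = []
    for g in genes:
        level = assoc_by_gene.get(g.symbol)
        if level == "strong":
            g2 = GeneRecord(
                g.symbol, g.refseq_id, g.interval,
                pLI=round(0.95 + 0.04 * rng.random(), 4),
                rvis_percentile=round(float(rng.uniform(1, 9)), 2),
                hi_percentile=round(float(rng.uniform(1, 9)), 2),
                clingen_hi_triplo=2, in_ddg2p=True, in_omim=True,
                modes_of_inheritance=frozenset({"AD"}),
                hpo_terms=frozenset(gene2hpo.get(g.symbol, ())),
            )
        elif level == "medium":
            g2 = GeneRecord(
                g.symbol, g.refseq_id, g.interval,
                pLI=round(float(rng.uniform(0, 0.5)), 4),
                rvis_percentile=round(float(rng.uniform(30, 90)), 2),
                hi_percentile=round(float(rng.uniform(30, 90)), 2),
                in_ddg2p=True, in_omim=True,
                modes_of_inheritance=frozenset({"AD"}),
                hpo_terms=frozenset(gene2hpo.get(g.symbol, ())),
            )
        elif level == "weak":
            g2 = GeneRecord(
                g.symbol, g.refseq_id, g.interval,
                pLI=round(float(rng.uniform(0, 0.5)), 4),
                in_omim=True,
                hpo_terms=frozenset(gene2hpo.get(g.symbol, ())),
            )
        else:  # decoy: at most one point, never phenotype-branch terms
            g2 = GeneRecord(
                g.symbol, g.refseq_id, g.interval,
                pLI=round(float(rng.uniform(0, 0.5)), 4),
                rvis_percentile=round(float(rng.uniform(20, 99)), 2),
                in_omim=bool(rng.random() < 0.3),
                hpo_terms=frozenset(gene2hpo.get(g.symbol, ())),
            )
        annotated.append(g2)
    genes = annotated
    gene_by_symbol = {g.symbol: g for g in genes}
    svio.write_gene_table(genes, out / "genes.tsv")

    # --- expression ----------------------------------------------------------
    expr = pd.DataFrame(
        np.round(rng.lognormal(mean=1.2, sigma=0.8, size=(len(genes), len(cell_types))), 4),
        index=[g.symbol for g in genes], columns=cell_types,
    )
    silent = rng.random(len(genes)) < 0.1
    expr.iloc[silent, :] = np.round(rng.uniform(0.0, 0.4, size=(int(silent.sum()), len(cell_types))), 4)
    for t in (t for t in targets if t is not None):
        for k, ct in enumerate(cell_types):
            expr.loc[t.symbol, ct] = round(10.0 - k + float(rng.uniform(0, 0.5)), 4)
    expr.index.name = "gene"
    expr.to_csv(out / "expression.tsv", sep="\t")

    # --- enhancers -----------------------------------------------------------
    cluster_iv: dict[str, tuple[int, int]] = {}  # target symbol -> cluster interval
    for i, (mode, _) in enumerate(plan):
        if mode == "position_enhancer_loss":
            t = targets[i]
            tad = gene_meta[t.symbol]["tad"]
            cluster_iv[t.symbol] = (tad[1] - margin - 150_000, tad[1] - margin)

    enhancers_by_ct: dict[str, dict[str, list[tuple[int, int]]]] = {}
    cluster_by_tad = {
        (gene_meta[sym]["chrom"], gene_meta[sym]["tad"]): iv
        for sym, iv in cluster_iv.items()
    }
    for ct in cell_types:
        enhancers_by_ct[ct] = {c: [] for c in chroms}
        for chrom in chroms:
            for tad in shared_tads[chrom]:
                key = (chrom, tad)
                role = tad_role.get(key)
                if role == "empty":
                    continue
                if key in cluster_by_tad:
                    lo, hi = cluster_by_tad[key]
                    starts = np.sort(rng.integers(lo, hi - 1_500, size=config.enhancer_cluster_size))
                    enhancers_by_ct[ct][chrom].extend((int(s), int(s) + 1_500) for s in starts)
                elif rng.random() < 0.6:
                    n_e = int(rng.integers(2, 6))
                    lo, hi = tad[0] + margin, tad[1] - margin - 1_500
                    if hi <= lo:  # clipped terminal TAD too small
                        continue
                    starts = np.sort(rng.integers(lo, hi, size=n_e))
                    enhancers_by_ct[ct][chrom].extend((int(s), int(s) + 1_500) for s in starts)
            enhancers_by_ct[ct][chrom].sort()
        svio.write_bed_intervals(enhancers_by_ct[ct], out / f"enhancers_{ct}.bed")
        svio.write_bed_intervals(tads_by_ct[ct], out / f"tads_{ct}.bed")

    # --- Hi-C: block structure with elevated intra-TAD signal ----------------
    for ci, ct in enumerate(cell_types):
        matrices = {}
        for xi, chrom in enumerate(chroms):
            n_bins = -(-sizes[chrom] // res)
            mids = (np.arange(n_bins) + 0.5) * res
            tad_id = np.full(n_bins, -1)
            for k, (s, e) in enumerate(tads_by_ct[ct][chrom]):
                tad_id[(mids >= s) & (mids < e)] = k
            same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
            lam = config.hic_base + config.intra_tad_boost * same
            mrng = np.random.default_rng([config.seed, 7, ci, xi])
            m = mrng.poisson(lam).astype(float)
            m = np.triu(m) + np.triu(m, 1).T  # symmetric
            matrices[chrom] = m
        svio.write_hic_triplets(matrices, out / f"hic_{ct}.tsv")

    # --- promoter interactions (PCHiC and DHS connections) -------------------
    def make_interactions(sub_rng) -> list[tuple[GenomicInterval, GenomicInterval]]:
        pairs = []
        for g in genes:
            tss = g.tss
            anchor = GenomicInterval(g.chrom, max(0, tss - 2_000), tss + 2_000)
            other_pos: list[int] = []
            if g.symbol in cluster_iv:
                lo, hi = cluster_iv[g.symbol]
                other_pos += [int(p) for p in sub_rng.integers(lo, hi, size=5)]
                other_pos += [int(p) for p in sub_rng.integers(
                    max(0, tss - 500_000), tss, size=2)]
            else:
                n_ix = int(sub_rng.integers(4, 10))
                lo = max(2_000, tss - 800_000)
                hi = min(sizes[g.chrom] - 6_000, tss + 800_000)
                other_pos += [int(p) for p in sub_rng.integers(lo, hi, size=n_ix)]
            for p in sorted(other_pos):
                pairs.append((anchor, GenomicInterval(g.chrom, p, p + 4_000)))
        return pairs

    pchic = make_interactions(np.random.default_rng([config.seed, 11]))
    dhs = make_interactions(np.random.default_rng([config.seed, 13]))
    svio.write_interaction_bedpe(pchic, out / "pchic.bedpe")
    svio.write_interaction_bedpe(dhs, out / "dhs.bedpe")

    # --- chrom sizes + resource config ---------------------------------------
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom in chroms:
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
    resources = {
        "cell_types": cell_types,
        "hic_resolution": res,
        "chrom_sizes": "chrom_sizes.tsv",
        "tads": {ct: f"tads_{ct}.bed" for ct in cell_types},
        "enhancers": {ct: f"enhancers_{ct}.bed" for ct in cell_types},
        "hic": {ct: f"hic_{ct}.tsv" for ct in cell_types},
        "expression": "expression.tsv",
        "pchic": "pchic.bedpe",
        "dhs": "dhs.bedpe",
    }
    with open(out / "resources.yaml", "w") as fh:
        yaml.safe_dump(resources, fh, sort_keys=True)

    # --- patient SVs, HPO profiles, DE tables --------------------------------
    gt_rows: list[GroundTruthRow] = []
    patients_manifest = []
    for i, (mode, assoc) in enumerate(plan):
        pid = patient_ids[i]
        prng = np.random.default_rng([config.seed, 23, i])
        junctions: list[BreakpointJunction] = []
        target = targets[i]
        if target is not None:
            chrom = target.chrom
            tad = gene_meta[target.symbol]["tad"]
            decoy_chrom = chroms[(chroms.index(chrom) + 1) % len(chroms)]
            if mode == "direct_del":
                s = max(0, target.interval.start - int(prng.integers(10_000, 40_000)))
                e = min(sizes[chrom], target.interval.end + int(prng.integers(10_000, 40_000)))
                junctions.append(BreakpointJunction(
                    f"{pid}_del", BreakpointEnd(chrom, s, "tail"),
                    BreakpointEnd(chrom, e, "head"), "DEL", pid))
            elif mode == "direct_trunc":
                p = int(prng.integers(target.interval.start + 1_000, target.interval.end - 1_000))
                q = int(prng.integers(0, sizes[decoy_chrom]))
                junctions.append(BreakpointJunction(
                    f"{pid}_tra", BreakpointEnd(chrom, p, "tail"),
                    BreakpointEnd(decoy_chrom, q, "head"), "TRA", pid))
            elif mode == "direct_dup":
                s = int(prng.integers(tad[0] + margin, target.interval.start - 5_000))
                e = int(prng.integers(target.interval.end + 5_000, tad[1] - margin))
                junctions.append(BreakpointJunction(
                    f"{pid}_dup", BreakpointEnd(chrom, s, "head"),
                    BreakpointEnd(chrom, e, "tail"), "DUP", pid))
            elif mode == "position_enhancer_loss":
                ensure_enhancer_bearing(enhancers_by_ct, chrom, tad)
                lo = target.interval.end + 2 * res
                hi = cluster_iv[target.symbol][0] - 2 * res
                p = int(prng.integers(lo, hi))
                q = int(prng.integers(0, sizes[decoy_chrom]))
                junctions.append(BreakpointJunction(
                    f"{pid}_pos", BreakpointEnd(chrom, p, "tail"),
                    BreakpointEnd(decoy_chrom, q, "head"), "TRA", pid))
        else:
            decoy_chrom = chroms[i % len(chroms)]
        for d in range(config.decoys_per_patient):
            s = int(prng.integers(0, sizes[decoy_chrom] - 300_000))
            e = s + int(prng.integers(50_000, 250_000))
            junctions.append(BreakpointJunction(
                f"{pid}_decoy{d}", BreakpointEnd(decoy_chrom, s, "tail"),
                BreakpointEnd(decoy_chrom, e, "head"),
                "DEL" if d % 2 == 0 else "INV", pid))
        svs = SVSet(patient_id=pid, junctions=junctions)
        sv_path = out / "patients" / f"{pid}.svs.bedpe"
        svio.write_sv_bedpe(svs, sv_path)
        hpo_path = out / "patients" / f"{pid}.hpo.tsv"
        svio.write_hpo_profile(profiles[i], hpo_path)

        # DE table: dosage-affected genes show reduced expression; a tandem
        # duplication shows a mild gain
        de_path = out / "patients" / f"{pid}.de.tsv"
        with open(de_path, "w") as fh:
            fh.write("gene\tlog2fc\tp\n")
            for g in genes:
                direct = classify_direct_effect(g, svs)
                if g.symbol == (target.symbol if target else None) and mode == "position_enhancer_loss":
                    lfc, p = -1.0 + float(prng.normal(0, 0.1)), float(prng.uniform(1e-5, 1e-3))
                elif direct.category in ("deleted", "truncated"):
                    lfc, p = -1.0 + float(prng.normal(0, 0.1)), float(prng.uniform(1e-5, 1e-3))
                elif direct.category == "duplicated":
                    lfc, p = 0.58 + float(prng.normal(0, 0.05)), float(prng.uniform(1e-5, 1e-3))
                else:
                    lfc, p = float(prng.normal(0, 0.15)), float(prng.uniform(0.1, 0.95))
                fh.write(f"{g.symbol}\t{lfc:.4f}\t{p:.6g}\n")

        if target is not None:
            effect = "strong" if mode in ("direct_del", "direct_trunc",
                                          "position_enhancer_loss") else "weak"
            expected = _EXPECTED_TIER[(assoc, effect)]
        else:
            expected = "none"
        gt_rows.append(GroundTruthRow(
            pid, mode, assoc, target.symbol if target else "",
            target.chrom if target else "", expected))
        patients_manifest.append({
            "id": pid, "svs": str(sv_path.relative_to(out)),
            "hpo": str(hpo_path.relative_to(out)), "de": str(de_path.relative_to(out)),
        })

    gt = pd.DataFrame([vars(r) for r in gt_rows])
    gt.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump({"patients": patients_manifest}, fh, sort_keys=True)

    cohort = SimulatedCohort(
        out_dir=out, config=config,
        resources_yaml=out / "resources.yaml",
        genes_tsv=out / "genes.tsv",
        gene2hpo_tsv=out / "gene2hpo.tsv",
        ontology_obo=out / "ontology.obo",
        ground_truth_tsv=out / "ground_truth.tsv",
        patients=patients_manifest,
        ground_truth=gt,
    )
    _verify_plantings(cohort, plan, targets, gene_by_symbol)
    return cohort


def _verify_plantings(cohort, plan, targets, gene_by_symbol) -> None:
    """Check planted position-effect drivers actually reach a strong support
    score through the real evaluation path, before the ground truth is used."""
    if not any(m == "position_enhancer_loss" for m, _ in plan):
        return
    bundle = svio.read_resource_bundle(cohort.resources_yaml)
    for i, (mode, _) in enumerate(plan):
        if mode != "position_enhancer_loss":
            continue
        pid = cohort.patients[i]
        svs = svio.read_sv_bedpe(cohort.out_dir / pid["svs"], pid["id"])
        de = svio.read_de_table(cohort.out_dir / pid["de"])
        ev = evaluate_position_effect(gene_by_symbol[targets[i].symbol], svs, bundle, de)
        if ev.support_score <= AnalysisConfig().support_strong:
            raise RuntimeError(
                f"planted position-effect driver {targets[i].symbol} for "
                f"{pid['id']} only reached support {ev.support_score}"
            )


def load_cohort(out_dir):
    """Load a simulated cohort back through the standard readers.

    Returns (genes, ontology, bundle, patients) where patients is a list of
    (SVSet, PhenotypeProfile, de_table) ready for the pipeline.
    """
    out = Path(out_dir)
    genes = svio.read_gene_table(out / "genes.tsv", out / "gene2hpo.tsv")
    ontology = Ontology.from_obo(out / "ontology.obo")
    ann = pd.read_csv(out / "gene2hpo.tsv", sep="\t", comment="#",
                      names=["symbol", "term"])
    gene2hpo: dict[str, set[str]] = {}
    for sym, term in zip(ann["symbol"], ann["term"]):
        gene2hpo.setdefault(sym, set()).add(term)
    ontology.set_annotations(gene2hpo)
    bundle = svio.read_resource_bundle(out / "resources.yaml")
    with open(out / "cohort.yaml") as fh:
        manifest = yaml.safe_load(fh)
    patients = []
    for p in manifest["patients"]:
        svs = svio.read_sv_bedpe(out / p["svs"], p["id"])
        profile = svio.read_hpo_profile(out / p["hpo"], p["id"], ontology)
        de = svio.read_de_table(out / p["de"])
        patients.append((svs, profile, de))
    return genes, ontology, bundle, patients
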