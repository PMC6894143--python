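"""Readers and writers for every input/output format of the workflow.

Coordinate handling: BED/BEDPE files are consumed as 0-based half-open;
VCF positions (1-based) are converted exactly once here. A deletion record
with POS=100, END=500 therefore becomes the internal interval [99, 500).

BEDPE orientation convention: strand '+' marks a breakpoint at the 3' end
of the retained segment (orientation "tail", segment extends to lower
coordinates), strand '-' an orientation "head" breakpoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classify import DriverCall, PatientSummary, sort_calls
from .model import (
    BreakpointEnd,
    BreakpointJunction,
    GeneRecord,
    GenomicInterval,
    PhenotypeProfile,
    SVSet,
)

logger = logging.getLogger(__name__)

_STRAND_TO_ORIENT = {"+": "tail", "-": "head"}
_ORIENT_TO_STRAND = {"tail": "+", "head": "-"}


# ---------------------------------------------------------------------------
# SV junctions: BEDPE and VCF
# ---------------------------------------------------------------------------

def read_sv_bedpe(path, patient_id: str = "") -> SVSet:
    """Read breakpoint junctions from a 10(+1)-column BEDPE file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 [sv_type]; the junction positions are start1/start2.
    """
    junctions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{line_no}: BEDPE needs >= 10 columns")
            sv_type = f[10] if len(f) > 10 and f[10] else "BND"
            junctions.append(
                BreakpointJunction(
                    id=f[6],
                    pos_a=BreakpointEnd(f[0], int(f[1]), _parse_strand(f[8], path, line_no)),
                    pos_b=BreakpointEnd(f[3], int(f[4]), _parse_strand(f[9], path, line_no)),
                    sv_type=sv_type,
                    patient_id=patient_id,
                )
            )
    return SVSet(patient_id=patient_id, junctions=junctions)


def _parse_strand(s: str, path, line_no: int) -> str:
    try:
        return _STRAND_TO_ORIENT[s]
    except KeyError:
        raise ValueError(f"{path}:{line_no}: malformed orientation {s!r}") from None


def write_sv_bedpe(svs: SVSet, path) -> None:
    with open(path, "w") as fh:
        for j in svs.junctions:
            fh.write(
                "\t".join(
                    [
                        j.pos_a.chrom,
                        str(j.pos_a.position),
                        str(j.pos_a.position + 1),
                        j.pos_b.chrom,
                        str(j.pos_b.position),
                        str(j.pos_b.position + 1),
                        j.id,
                        ".",
                        _ORIENT_TO_STRAND[j.pos_a.orientation],
                        _ORIENT_TO_STRAND[j.pos_b.orientation],
                        j.sv_type,
                    ]
                )
                + "\n"
            )


def read_sv_vcf(path, patient_id: str = "") -> SVSet:
    """Read SVs from a VCF 4.2 file with SVTYPE/END/MATEID annotation.

    DEL/DUP/INV/INS records become one junction with the span edges as
    breakpoint ends; BND records are paired by MATEID and emitted once per
    mate pair. Unpaired BND records are an error.
    """
    from cyvcf2 import VCF

    junctions = []
    bnd: dict[str, object] = {}
    emitted: set[str] = set()
    for v in VCF(str(path)):
        svtype = v.INFO.get("SVTYPE") or "BND"
        if svtype == "BND":
            vid = v.ID
            mate = v.INFO.get("MATEID")
            if mate is None:
                raise ValueError(f"BND record {vid} has no MATEID")
            if mate in bnd:
                m = bnd.pop(mate)
                junctions.append(_bnd_pair_to_junction(m, v, patient_id))
                emitted.add(vid)
                emitted.add(mate)
            else:
                bnd[vid] = v
        else:
            start = v.start  # 0-based (POS - 1)
            end = v.INFO.get("END")
            if end is None:
                raise ValueError(f"record {v.ID}: symbolic SV without END")
            orient = {
                "DEL": ("tail", "head"),
                "DUP": ("head", "tail"),
                "INV": ("head", "head"),
                "INS": ("tail", "head"),
            }[svtype]
            junctions.append(
                BreakpointJunction(
                    id=v.ID or f"{v.CHROM}_{start}_{svtype}",
                    pos_a=BreakpointEnd(v.CHROM, start, orient[0]),
                    pos_b=BreakpointEnd(v.CHROM, int(end), orient[1]),
                    sv_type=svtype,
                    patient_id=patient_id,
                )
            )
    if bnd:
        raise ValueError(f"unpaired BND records: {sorted(bnd)}")
    return SVSet(patient_id=patient_id, junctions=junctions)


def _bnd_pair_to_junction(a, b, patient_id: str) -> BreakpointJunction:
    return BreakpointJunction(
        id=str(a.ID),
        pos_a=BreakpointEnd(a.CHROM, a.start, _bnd_local_orientation(a.ALT[0])),
        pos_b=BreakpointEnd(b.CHROM, b.start, _bnd_local_orientation(b.ALT[0])),
        sv_type="BND",
        patient_id=patient_id,
    )


def _bnd_local_orientation(alt: str) -> str:
    """Local-end orientation from a VCF breakend ALT string.

    ``t[p[`` / ``t]p]`` — the local piece ends at this base (tail);
    ``[p[t`` / ``]p]t`` — the local piece starts here (head).
    """
    if alt[0] not in "[]":
        return "tail"
    return "head"


# ---------------------------------------------------------------------------
# phenotype profiles
# ---------------------------------------------------------------------------

def read_hpo_profile(path, patient_id: str = "", ontology=None) -> PhenotypeProfile:
    """Read a patient HPO profile from a TSV: one term per line, with
    optional ``#patient:`` and ``#sex:`` headers; terms are validated against
    the ontology when one is supplied."""
    terms = []
    sex = "unknown"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#patient:"):
                    patient_id = line.split(":", 1)[1].strip()
                elif line.lower().startswith("#sex:"):
                    sex = line.split(":", 1)[1].strip()
                continue
            terms.append(line.split("\t")[0])
    profile = PhenotypeProfile(patient_id=patient_id, hpo_terms=frozenset(terms), sex=sex)
    if ontology is not None:
        ontology.validate_terms(profile.hpo_terms)
    return profile


def write_hpo_profile(profile: PhenotypeProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#patient: {profile.patient_id}\n#sex: {profile.sex}\n")
        for term in sorted(profile.hpo_terms):
            fh.write(term + "\n")


def read_patient_inputs(
    sv_path, hpo_path, sv_format: str = "bedpe", patient_id: str = "", ontology=None
) -> tuple[SVSet, PhenotypeProfile]:
    """Convenience loader for one patient's SV junctions and HPO profile."""
    if sv_format == "bedpe":
        svs = read_sv_bedpe(sv_path, patient_id)
    elif sv_format == "vcf":
        svs = read_sv_vcf(sv_path, patient_id)
    else:
        raise ValueError(f"unknown SV format {sv_format!r}")
    profile = read_hpo_profile(hpo_path, patient_id or svs.patient_id, ontology)
    if not svs.patient_id:
        svs.patient_id = profile.patient_id
    return svs, profile


# ---------------------------------------------------------------------------
# gene annotation table
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = [
    "symbol", "chrom", "start", "end", "strand", "refseq_id",
    "pLI", "rvis_pct", "hi_pct", "clingen_score", "ddg2p", "omim", "moi",
]


def read_gene_table(path, gene2hpo_path=None) -> list[GeneRecord]:
    """Read the gene annotation TSV; rows missing a symbol or RefSeq id are
    dropped (not protein-coding). Optional second file attaches HPO terms
    (two columns: symbol, term id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    gene2hpo: dict[str, set[str]] = {}
    if gene2hpo_path is not None:
        ann = pd.read_csv(
            gene2hpo_path, sep="\t", dtype=str, keep_default_na=False,
            comment="#", names=["symbol", "term"], usecols=[0, 1],
        )
        for sym, term in zip(ann["symbol"], ann["term"]):
            gene2hpo.setdefault(sym, set()).add(term)
    genes = []
    for row in df.itertuples(index=False):
        if not row.symbol or not row.refseq_id:
            logger.debug("dropping non-protein-coding row %r", row.symbol)
            continue
        genes.append(
            GeneRecord(
                symbol=row.symbol,
                refseq_id=row.refseq_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                pLI=_opt_float(row.pLI),
                rvis_percentile=_opt_float(row.rvis_pct),
                hi_percentile=_opt_float(row.hi_pct),
                clingen_hi_triplo=_opt_int(row.clingen_score),
                in_ddg2p=_parse_bool(row.ddg2p),
                in_omim=_parse_bool(row.omim),
                modes_of_inheritance=frozenset(m for m in row.moi.split(",") if m),
                hpo_terms=frozenset(gene2hpo.get(row.symbol, ())),
            )
        )
    return genes


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", "NA", "nan") else None


def _opt_int(s: str) -> Optional[int]:
    return int(s) if s not in ("", "NA", "nan") else None


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes")


def write_gene_table(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.symbol, g.interval.chrom, str(g.interval.start),
                        str(g.interval.end), g.interval.strand, g.refseq_id,
                        _fmt_opt(g.pLI), _fmt_opt(g.rvis_percentile),
                        _fmt_opt(g.hi_percentile), _fmt_opt(g.clingen_hi_triplo),
                        "1" if g.in_ddg2p else "0", "1" if g.in_omim else "0",
                        ",".join(sorted(g.modes_of_inheritance)),
                    ]
                )
                + "\n"
            )


def _fmt_opt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


# ---------------------------------------------------------------------------
# resource bundle
# ---------------------------------------------------------------------------

@dataclass
class ResourceBundle:
    """Tissue-specific regulatory datasets, indexed for interval queries.

    ``cell_types`` is the join key across tads/hic/enhancers/expression.
    Interval collections are plain per-chromosome (start, end) lists; at the
    scale this tool operates on (genes near a patient's SVs) linear scans
    are exact and fast.
    """

    cell_types: list[str]
    hic_resolution: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    tads: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    hic: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    enhancers: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    expression: Optional[pd.DataFrame] = None
    pchic: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)
    dhs: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """BED3+ reader; intervals are kept exactly as stated (no merging)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{line_no}: BED needs >= 3 columns")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bed_intervals(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_interaction_bedpe(path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """PCHiC / DHS connection pairs from a BEDPE file (first 6 columns)."""
    pairs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{line_no}: BEDPE needs >= 6 columns")
            pairs.append(
                (
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                )
            )
    return pairs


def write_interaction_bedpe(pairs, path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def read_hic_triplets(path, resolution: int, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Read a binned Hi-C matrix from 4-column triplets
    (chrom, bin_i, bin_j, normalized count) into dense symmetric arrays."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "bin_i", "bin_j", "value"],
        dtype={"chrom": str, "bin_i": int, "bin_j": int, "value": float},
    )
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        if chrom not in chrom_sizes:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        n_bins = -(-chrom_sizes[chrom] // resolution)
        i = sub["bin_i"].to_numpy()
        j = sub["bin_j"].to_numpy()
        if i.max(initial=-1) >= n_bins or j.max(initial=-1) >= n_bins:
            raise ValueError(
                f"{path}: bin index exceeds {n_bins} bins expected for "
                f"{chrom} at {resolution} bp resolution"
            )
        m = np.zeros((n_bins, n_bins))
        m[i, j] = sub["value"].to_numpy()
        m[j, i] = sub["value"].to_numpy()
        out[chrom] = m
    return out


def write_hic_triplets(matrices: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(matrices):
            m = matrices[chrom]
            iu, ju = np.nonzero(np.triu(m))
            for i, j in zip(iu, ju):
                fh.write(f"{chrom}\t{i}\t{j}\t{m[i, j]:.6g}\n")


def read_expression_table(path) -> pd.DataFrame:
    """Gene x cell-type RPKM table (first column: gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def read_de_table(path) -> pd.DataFrame:
    """Patient differential-expression table: gene, log2fc, p."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    need = {"gene", "log2fc", "p"}
    if not need <= set(df.columns):
        raise ValueError(f"DE table needs columns {sorted(need)}")
    return df.set_index("gene")[["log2fc", "p"]].astype(float)


def gene_rpkm(expression: Optional[pd.DataFrame], symbol: str, cell_type: str) -> float:
    """RPKM lookup; genes absent from the table count as not expressed (0)."""
    if expression is None or symbol not in expression.index:
        logger.debug("gene %s absent from expression table; RPKM treated as 0", symbol)
        return 0.0
    return float(expression.loc[symbol, cell_type])


def read_resource_bundle(config_path) -> ResourceBundle:
    """Load every regulatory resource named in a YAML config.

    Relative paths resolve against the config file's directory. Missing
    optional resources are recorded as absent; duplicate cell-type labels
    and Hi-C matrices inconsistent with the declared resolution are errors.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    cell_types = list(cfg["cell_types"])
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("duplicate cell-type labels in resource config")

    def resolve(p):
        return base / p

    chrom_sizes: dict[str, int] = {}
    if "chrom_sizes" in cfg:
        with open(resolve(cfg["chrom_sizes"])) as fh:
            for line in fh:
                if line.strip():
                    c, size = line.split()[:2]
                    chrom_sizes[c] = int(size)

    bundle = ResourceBundle(
        cell_types=cell_types,
        hic_resolution=int(cfg.get("hic_resolution", 0)),
        chrom_sizes=chrom_sizes,
    )
    for ct, path in (cfg.get("tads") or {}).items():
        _check_ct(ct, cell_types)
        bundle.tads[ct] = read_bed_intervals(resolve(path))
    for ct, path in (cfg.get("enhancers") or {}).items():
        _check_ct(ct, cell_types)
        bundle.enhancers[ct] = read_bed_intervals(resolve(path))
    for ct, path in (cfg.get("hic") or {}).items():
        _check_ct(ct, cell_types)
        if not bundle.hic_resolution:
            raise ValueError("hic_resolution required when Hi-C matrices are given")
        bundle.hic[ct] = read_hic_triplets(resolve(path), bundle.hic_resolution, chrom_sizes)
    if cfg.get("expression"):
        bundle.expression = read_expression_table(resolve(cfg["expression"]))
    if cfg.get("pchic"):
        bundle.pchic = read_interaction_bedpe(resolve(cfg["pchic"]))
    if cfg.get("dhs"):
        bundle.dhs = read_interaction_bedpe(resolve(cfg["dhs"]))
    return bundle


def _check_ct(ct: str, cell_types: list[str]) -> None:
    if ct not in cell_types:
        raise ValueError(f"resource for unknown cell type {ct!r}")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

DRIVER_COLUMNS = [
    "patient_id", "gene", "tier", "association", "effect", "effect_basis",
    "direct_category", "distance_bp", "disease_score", "total_phenomatch",
    "n_low_phenomatch", "n_high_phenomatch", "pct_high_phenomatch",
    "moi_compatible", "support_score", "tad_disrupted", "enhancers_lost",
    "v4c_disrupted", "pchic_disrupted", "dhs_disrupted", "expression_changed",
]


def write_driver_report(
    calls: list[DriverCall],
    summaries: list[PatientSummary],
    cohort: dict,
    out_dir,
) -> None:
    """Write drivers.tsv / patients.tsv / cohort.json with deterministic
    ordering (identical inputs give byte-identical files)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "drivers.tsv", "w") as fh:
        fh.write("\t".join(DRIVER_COLUMNS) + "\n")
        for c in sort_calls(calls):
            pm = c.association.phenomatch
            comp = c.position_evidence.components if c.position_evidence else {}
            fh.write(
                "\t".join(
                    [
                        c.patient_id, c.symbol, c.tier, c.association.strength,
                        c.effect.strength, c.effect_basis, c.direct_category,
                        str(c.distance_bp), str(c.association.disease_score.total),
                        f"{pm.total_score:.4f}", str(pm.n_low), str(pm.n_high),
                        f"{pm.pct_high:.2f}",
                        "1" if c.association.moi_compatible else "0",
                        str(c.position_evidence.support_score if c.position_evidence else 0),
                    ]
                    + ["1" if comp.get(name, False) else "0" for name in (
                        "tad_disrupted", "enhancers_lost", "v4c_disrupted",
                        "pchic_disrupted", "dhs_disrupted", "expression_changed")]
                )
                + "\n"
            )

    with open(out_dir / "patients.tsv", "w") as fh:
        fh.write("patient_id\tn_T1\tn_T2\tn_T3\tpct_hpo_explained\texplained\tdriver_category\n")
        for s in sorted(summaries, key=lambda s: s.patient_id):
            fh.write(
                f"{s.patient_id}\t{s.n_T1}\t{s.n_T2}\t{s.n_T3}\t"
                f"{s.pct_hpo_explained:.2f}\t{s.explained}\t{s.driver_category}\n"
            )

    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(cohort, fh, indent=2, sort_keys=True)
        fh.write("\n")
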