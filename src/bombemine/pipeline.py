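"""Orchestration of the discovery and orthology-evidence stages.

``run_discovery`` chains ORF extraction, precursor annotation, ranking,
and family clustering over a nucleotide or protein FASTA.
``run_orthology`` combines three independent evidence lines for each
query precursor: conserved alignment columns shared with a reference
group, clade membership in a bootstrapped NJ tree, and shared intron
position/phase.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import seq_io
from .annotate import annotate_precursor, PrecursorAnnotation
from .families import ClusterParams, cluster_families, PeptideFamily
from .align import progressive_msa, conserved_columns, Alignment
from .genestruct import GeneModel, map_introns_to_alignment
from .phylo import bootstrap_support, is_in_clade_with


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one place."""

    dibasic_set: tuple[str, ...] = ("KR", "RR")
    allow_monobasic: bool = False
    min_len: int = 4
    max_len: int = 40
    min_orf_aa: int = 60
    motifs: tuple[str, ...] = ("GPxxG",)
    top_k: int = 5000
    cluster_terminus: str = "C"
    cluster_k: int = 6
    cluster_m: int = 4
    cross_species_only: bool = False
    min_b: int = 3
    boot_reps: int = 1000
    seed: int = 17

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class DiscoveryReport:
    annotations: list[PrecursorAnnotation]   # ranked, top_k retained
    families: list[PeptideFamily]
    log: dict

    def ranking_table(self) -> pd.DataFrame:
        rows = []
        for rank, ann in enumerate(self.annotations, 1):
            sig = ann.signal or ("", "")
            rows.append({
                "rank": rank, "id": ann.record.id, "score": ann.score,
                "signal_start": sig[0], "signal_end": sig[1],
                "n_peptides": len(ann.peptides),
                "n_amidated": sum(p.amidated for p in ann.peptides),
            })
        return pd.DataFrame(rows)


def run_discovery(records: Sequence[seq_io.SeqRecord] | str | Path,
                  config: PipelineConfig = PipelineConfig(),
                  alphabet: str = "protein") -> DiscoveryReport:
    """Annotate, score, rank, and cluster candidate precursors.

    ``records`` may be a FASTA path or a list of records. Nucleotide
    input is expanded to six-frame stop-to-stop ORFs of at least
    ``min_orf_aa`` residues first.
    """
    if isinstance(records, (str, Path)):
        records = seq_io.read_fasta(records, alphabet=alphabet)
    if not records:
        raise ValueError("empty input")
    if alphabet == "dna":
        orfs = []
        for rec in records:
            orfs.extend(seq_io.six_frame_orfs(rec.residues,
                                              min_aa=config.min_orf_aa,
                                              parent_id=rec.id))
        proteins = seq_io.orf_protein_records(orfs)
    else:
        proteins = list(records)
    annotations = [
        annotate_precursor(rec, dibasic_set=config.dibasic_set,
                           allow_monobasic=config.allow_monobasic,
                           min_len=config.min_len, max_len=config.max_len,
                           motifs=config.motifs)
        for rec in proteins
    ]
    annotations.sort(key=lambda a: (-a.score, a.record.id))
    retained = annotations[:config.top_k]
    peptides = [p for ann in retained for p in ann.peptides]
    params = ClusterParams(terminus=config.cluster_terminus,
                           k=config.cluster_k, m=config.cluster_m,
                           cross_species_only=config.cross_species_only)
    families = cluster_families(peptides, params)
    log = {
        "n_input": len(records),
        "n_proteins": len(proteins),
        "n_retained": len(retained),
        "n_peptides": len(peptides),
        "n_families": len(families),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    return DiscoveryReport(annotations=retained, families=families, log=log)


@dataclass
class OrthologyEvidence:
    query: str
    conserved_column_count: int
    in_reference_clade: Optional[bool]
    clade_support: Optional[float]
    shared_intron: Optional[bool]   # None = n/a (no gene models)


def run_orthology(records: Sequence[seq_io.SeqRecord],
                  group_a_ids: Sequence[str],
                  group_b_ids: Sequence[str],
                  outgroup_ids: Sequence[str],
                  gene_models: Optional[dict[str, tuple[GeneModel, str]]] = None,
                  config: PipelineConfig = PipelineConfig(),
                  ) -> tuple[list[OrthologyEvidence], Alignment]:
    """Three-line orthology evidence for each group-A (query) record.

    Evidence lines per query: (1) conserved columns shared between the
    query's group and >= ``min_b`` group-B rows; (2) membership of the
    query in a clade with group-B references after outgroup rooting of
    the bootstrapped NJ tree; (3) an intron of equal phase in the same
    protein-alignment column as another species (n/a without gene
    models).
    """
    if not outgroup_ids:
        raise ValueError("outgroup required")
    msa = progressive_msa(records)
    cols = conserved_columns(msa, group_a_ids, group_b_ids,
                             min_b=min(config.min_b, len(group_b_ids)))
    tree, support = bootstrap_support(msa, n_reps=min(config.boot_reps, 200),
                                      seed=config.seed)
    intron_table = None
    if gene_models:
        rows = {rid: g for rid, g in msa.rows if rid in gene_models}
        intron_table = map_introns_to_alignment(gene_models, rows)
    out = []
    for q in group_a_ids:
        in_clade, clade = is_in_clade_with(tree, q, list(group_b_ids),
                                           list(outgroup_ids))
        # support of the smallest bipartition compatible with the clade
        sup = support.get(frozenset(clade))
        shared = None
        if intron_table is not None:
            qrows = [r for r in intron_table if r["species"] == q]
            shared = any(r["shared"] for r in qrows) if qrows else False
        out.append(OrthologyEvidence(
            query=q, conserved_column_count=len(cols),
            in_reference_clade=in_clade, clade_support=sup,
            shared_intron=shared))
    return out, msa
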