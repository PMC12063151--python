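"""End-to-end orchestration: filter cascade -> positional classes ->
triplex interactions -> pair labelling -> correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import coding as cp
from .expression import (
    aggregate_to_gene,
    correlate_genes,
    label_pairs,
    normalize_and_transform,
    summarize_by_group,
)
from .filtering import (
    FilterReport,
    HitPolicy,
    apply_hits_filters,
    compute_tpm,
    filter_expression,
    filter_length,
    filter_sense_exon_overlap,
    intersect_filters,
)
from .genomics import AnnotationSet, extract_transcript_sequence
from .positional import PositionalCall, classify_all
from .triplex import (
    TriplexParams,
    assign_interaction_context,
    classify_genome_context,
    interaction_pairs,
    scan_genome,
)


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def train_reference_hexamer_model(
    reference: AnnotationSet, genome: Mapping[str, str], seed: int = 0
) -> cp.HexamerModel:
    """Hexamer model from the reference annotation: in-frame hexamers of
    annotated ORFs vs annotated ncRNAs plus shuffled coding sequences."""
    rng = np.random.default_rng(seed)
    coding_seqs, noncoding_seqs = [], []
    for t in reference:
        seq = extract_transcript_sequence(t, genome)
        if t.biotype == "coding":
            orf = cp.find_longest_orf(seq, 0)
            coding_seqs.append(seq[orf.start : orf.end] if orf else seq)
            noncoding_seqs.append(_shuffled(seq, rng))
        else:
            noncoding_seqs.append(seq)
    return cp.train_hexamer_model(coding_seqs, noncoding_seqs)


def run_filter_cascade(
    candidates: AnnotationSet,
    reference: AnnotationSet,
    genome: Mapping[str, str],
    counts: pd.DataFrame,
    hits: Optional[pd.DataFrame] = None,
    policy: Optional[HitPolicy] = None,
    min_len: int = 200,
    min_tpm: float = 1.0,
    external_votes: Optional[Mapping[str, List[str]]] = None,
    hexamer_model: Optional[cp.HexamerModel] = None,
    seed: int = 0,
) -> Tuple[FilterReport, Dict[str, str]]:
    """The full candidate -> lncRNA filter cascade.

    Returns the FilterReport and the per-candidate coding/noncoding vote.
    ``counts`` is transcript-level over the candidate ids (reference
    transcripts may be present too and are used for the TPM denominator).
    """
    length_flags = filter_length(candidates, min_len)
    overlap_flags = filter_sense_exon_overlap(candidates, reference)

    if hexamer_model is None:
        hexamer_model = train_reference_hexamer_model(reference, genome, seed=seed)
    votes: Dict[str, str] = {}
    noncoding_flags: Dict[str, bool] = {}
    for t in candidates:
        seq = extract_transcript_sequence(t, genome)
        feats = cp.compute_features(seq, hexamer_model)
        ext = list((external_votes or {}).get(t.transcript_id, []))
        label = cp.classify_and_vote(feats, votes=ext)
        votes[t.transcript_id] = label
        noncoding_flags[t.transcript_id] = label == "noncoding"

    cand_ids = [t.transcript_id for t in candidates]
    if hits is not None and not hits.empty:
        known_rna_ok, domain_ok, _notes = apply_hits_filters(hits, cand_ids, policy)
    else:
        known_rna_ok = {i: True for i in cand_ids}
        domain_ok = {i: True for i in cand_ids}

    lengths = {t.transcript_id: t.spliced_length for t in candidates}
    lengths.update({t.transcript_id: t.spliced_length for t in reference})
    present = [i for i in counts.index if i in lengths]
    tpm = compute_tpm(counts.loc[present].astype(float), lengths)
    tpm_cand = tpm.loc[[i for i in cand_ids if i in tpm.index]]
    expressed = filter_expression(tpm_cand, min_tpm)
    for i in cand_ids:
        expressed.setdefault(i, False)

    report = intersect_filters(
        {
            "length_ok": length_flags,
            "no_sense_overlap": overlap_flags,
            "noncoding_vote": noncoding_flags,
            "known_rna_ok": known_rna_ok,
            "domain_ok": domain_ok,
            "expressed": expressed,
        }
    )
    return report, votes


@dataclass
class PipelineResult:
    report: FilterReport
    lncs: AnnotationSet
    positional: List[PositionalCall]
    interactions: list
    pairs: Dict[str, pd.DataFrame]
    pair_labels: pd.DataFrame
    correlations: pd.DataFrame
    context_fractions: Dict[str, float]


def run_pipeline(
    candidates: AnnotationSet,
    reference: AnnotationSet,
    genome: Mapping[str, str],
    counts: pd.DataFrame,
    design: pd.DataFrame,
    de_table: Optional[pd.DataFrame] = None,
    hits: Optional[pd.DataFrame] = None,
    triplex_params: Optional[TriplexParams] = None,
    context_promoter: Tuple[int, int] = (1000, 250),
    pair_promoter: Tuple[int, int] = (1500, 250),
    neighbour_window: int = 2000,
    seed: int = 0,
) -> PipelineResult:
    """Filter candidates, classify retained lncRNAs, predict triplexes,
    label lncRNA-gene pairs and correlate their expression."""
    report, _votes = run_filter_cascade(
        candidates, reference, genome, counts, hits=hits, seed=seed
    )
    retained = set(report.retained_ids)
    lncs = AnnotationSet(
        [t for t in candidates if t.transcript_id in retained],
        dict(candidates.chrom_lengths),
    )
    coding = reference.subset(["coding"])
    positional = classify_all(lncs, coding)

    params = triplex_params or TriplexParams()
    interactions = scan_genome(lncs, genome, params)
    context = classify_genome_context(reference, context_promoter)
    interactions = assign_interaction_context(interactions, context)
    pairs = interaction_pairs(interactions, coding, pair_promoter)

    pair_labels = label_pairs(lncs, coding, pairs, window=neighbour_window)

    gene_of = {t.transcript_id: t.gene_id for t in list(reference) + list(candidates)}
    gene_counts = aggregate_to_gene(
        counts.loc[[i for i in counts.index if i in gene_of]].astype(float), gene_of
    )
    transformed = normalize_and_transform(gene_counts.astype(float))
    wanted = list(zip(pair_labels["lnc_id"], pair_labels["gene_id"]))
    correlations = correlate_genes(transformed, wanted)
    pair_labels = pair_labels.merge(correlations, on=["lnc_id", "gene_id"], how="left")

    return PipelineResult(
        report=report,
        lncs=lncs,
        positional=positional,
        interactions=interactions,
        pairs=pairs,
        pair_labels=pair_labels,
        correlations=correlations,
        context_fractions=context.fractions(),
    )
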