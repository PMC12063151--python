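"""Seeded synthetic data with recorded ground truth for every pipeline
stage: genome + annotation with planted lncRNAs of every positional class
and per-filter decoys, planted promoter triplex sites, and a replicated
multi-condition count matrix with planted correlations and DE calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coding import fickett_score, find_longest_orf
from .filtering import compute_tpm
from .genomics import (
    AnnotationSet,
    GenomicInterval,
    TranscriptRecord,
    extract_transcript_sequence,
    reverse_complement,
)

POSITIONAL_CLASSES = (
    "antisense_exonic",
    "divergent",
    "convergent",
    "upstream_sense",
    "downstream_sense",
)

DECOY_FILTERS = {
    "decoy_short": "length_ok",
    "decoy_sense": "no_sense_overlap",
    "decoy_coding": "noncoding_vote",
    "decoy_silent": "expressed",
    "decoy_rfam": "known_rna_ok",
}

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    seed: int
    params: Dict[str, object] = field(default_factory=dict)
    lnc_classes: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    # lnc transcript id -> (positional class, partner gene id)
    lnc_gene_of: Dict[str, str] = field(default_factory=dict)
    decoys: Dict[str, str] = field(default_factory=dict)  # id -> intended filter
    planted_tts: List[Dict[str, object]] = field(default_factory=list)
    de_genes: Dict[str, float] = field(default_factory=dict)  # gene -> log2FC sign*mag
    pair_rho: List[Tuple[str, str, float]] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "lnc_classes": {k: list(v) for k, v in self.lnc_classes.items()},
            "lnc_gene_of": self.lnc_gene_of,
            "decoys": self.decoys,
            "planted_tts": self.planted_tts,
            "de_genes": self.de_genes,
            "pair_rho": [list(x) for x in self.pair_rho],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SyntheticDataset:
    genome: Dict[str, str]
    reference: AnnotationSet   # coding genes + annotated ncRNAs
    candidates: AnnotationSet  # planted lncRNAs + decoys (novel transcripts)
    hits: pd.DataFrame         # external-hit table exercising the hit filters
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _codon_table() -> Tuple[List[str], np.ndarray]:
    """Non-stop codons with a deterministic usage bias (codons with A/T in
    the middle position are favoured), giving coding sequences a hexamer
    and periodicity signal distinguishable from random DNA."""
    codons, weights = [], []
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                cod = a + b + c
                if cod in _STOPS:
                    continue
                codons.append(cod)
                weights.append(3.0 if b in "AT" else 1.0)
    w = np.array(weights)
    return codons, w / w.sum()


_CODONS, _CODON_P = _codon_table()


def _coding_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS, size=n_codons, p=_CODON_P))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + body + stop


def _noncoding_seq(rng: np.random.Generator, n: int, gc: float, max_tries: int = 50) -> str:
    """Random sequence guaranteed to look noncoding to the built-in
    classifier (no ORF > 100 aa, Fickett below the coding cutoff)."""
    for _ in range(max_tries):
        seq = "".join(_random_seq(rng, n, gc))
        if find_longest_orf(seq, 100) is None and fickett_score(seq, warn_short=False) <= 0.9:
            return seq
    raise RuntimeError("could not draw a noncoding-looking sequence")


# ---------------------------------------------------------------------------
# genome + annotation generator
# ---------------------------------------------------------------------------

def generate_genome_annotation(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 200_000,
    n_genes: int = 60,
    gc: float = 0.41,
    n_ncrna: int = 6,
    lncs_per_class: int = 3,
) -> SyntheticDataset:
    """Multi-chromosome genome with coding genes, ncRNAs, planted novel
    transcripts of every positional class, and per-filter decoys.

    Deterministic for a fixed seed; raises when the requested features do
    not fit into ``n_chrom * chrom_len`` bases.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_seqs = {c: _random_seq(rng, chrom_len, gc) for c in chrom_names}

    reference = AnnotationSet([], {c: chrom_len for c in chrom_names})
    candidates = AnnotationSet([], {c: chrom_len for c in chrom_names})
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_chrom=n_chrom, chrom_len=chrom_len, n_genes=n_genes, gc=gc,
            n_ncrna=n_ncrna, lncs_per_class=lncs_per_class,
        ),
    )

    # cassette plan: companion class per gene index (None = plain gene)
    companions: List[Optional[str]] = []
    for cls in POSITIONAL_CLASSES:
        companions.extend([cls] * lncs_per_class)
    companions.append("decoy_sense")
    while len(companions) < n_genes:
        companions.append(None)
    if len(companions) > n_genes:
        raise ValueError("n_genes too small for the requested planted classes")

    cursors = {c: 2000 for c in chrom_names}
    lnc_counter = 0

    def _write(chrom: str, start: int, seq: str) -> None:
        arr = chrom_seqs[chrom]
        if start < 0 or start + len(seq) > len(arr):
            raise ValueError("infeasible packing: feature beyond chromosome end")
        arr[start : start + len(seq)] = list(seq)

    def _place(chrom: str, length: int) -> int:
        gap = int(rng.integers(400, 900))
        start = cursors[chrom] + gap
        if start + length + 2000 > chrom_len:
            raise ValueError(
                "infeasible packing: increase chrom_len or reduce feature count"
            )
        cursors[chrom] = start + length
        return start

    for gi, companion in enumerate(companions):
        chrom = chrom_names[gi % n_chrom]
        gene_id = f"gene{gi:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(150, 301))
        orf = _coding_orf(rng, n_codons)
        utr5, utr3 = 30, 30
        glen = utr5 + len(orf) + utr3

        # local layout: gene occupies [margin, margin + glen)
        margin = 1800  # room for 5'-side companions
        cassette_len = margin + glen + 1800
        cstart = _place(chrom, cassette_len)
        gstart = cstart + margin
        gene_seq = (
            "".join(_random_seq(rng, utr5, gc)) + orf + "".join(_random_seq(rng, utr3, gc))
        )
        _write(chrom, gstart, gene_seq if strand == "+" else reverse_complement(gene_seq))
        gene_iv = GenomicInterval(chrom, gstart, gstart + glen, strand)
        reference.add(
            TranscriptRecord(f"{gene_id}.t1", gene_id, gene_iv, [gene_iv], "coding")
        )

        if companion is None:
            continue
        if companion == "decoy_sense":
            # same strand, overlapping the gene exon tail by 100 bases
            dlen = 400
            if strand == "+":
                dstart = gene_iv.end - 100
            else:
                dstart = gene_iv.start - (dlen - 100)
            div = GenomicInterval(chrom, dstart, dstart + dlen, strand)
            candidates.add(TranscriptRecord("decoy_sense.t1", "decoy_sense", div, [div]))
            truth.decoys["decoy_sense.t1"] = DECOY_FILTERS["decoy_sense"]
            continue

        lnc_counter += 1
        lnc_gene = f"lncg{lnc_counter:02d}"
        lnc_tid = f"lnc{lnc_counter:02d}.t1"
        if companion == "antisense_exonic":
            # straddle a gene boundary: a short stretch of antisense exon
            # overlap plus random flanking sequence, so the transcript keeps
            # the class-defining overlap but still looks noncoding
            llen = int(rng.integers(220, 300))
            lstrand = "-" if strand == "+" else "+"
            chosen = None
            for _ in range(40):
                inside = int(rng.integers(60, 140))
                outside = llen - inside
                if rng.random() < 0.5:
                    iv = GenomicInterval(
                        chrom, gene_iv.start - outside, gene_iv.start + inside, lstrand
                    )
                else:
                    iv = GenomicInterval(
                        chrom, gene_iv.end - inside, gene_iv.end + outside, lstrand
                    )
                seq = "".join(chrom_seqs[chrom][iv.start : iv.end])
                if lstrand == "-":
                    seq = reverse_complement(seq)
                if fickett_score(seq, warn_short=False) <= 0.9:
                    chosen = iv
                    break
            if chosen is None:
                raise RuntimeError("could not place a noncoding-looking antisense lncRNA")
            lnc_exons = [chosen]
        else:
            llen = int(rng.integers(250, 600))
            if companion in ("divergent", "convergent"):
                lstrand = "-" if strand == "+" else "+"
                gap = int(rng.integers(200, 800))
            else:
                lstrand = strand
                gap = int(rng.integers(300, 1500))
            five_prime_side = companion in ("divergent", "upstream_sense")
            left = five_prime_side if strand == "+" else not five_prime_side
            if left:
                lstart = gene_iv.start - gap - llen
            else:
                lstart = gene_iv.end + gap
            seq = _noncoding_seq(rng, llen, gc)
            _write(chrom, lstart, seq if lstrand == "+" else reverse_complement(seq))
            if companion == "divergent" and llen >= 400:
                # make some planted lncRNAs multi-exonic
                e1 = GenomicInterval(chrom, lstart, lstart + 150, lstrand)
                e2 = GenomicInterval(chrom, lstart + 250, lstart + llen, lstrand)
                lnc_exons = [e1, e2]
            else:
                lnc_exons = [GenomicInterval(chrom, lstart, lstart + llen, lstrand)]
        candidates.add(TranscriptRecord.from_exons(lnc_tid, lnc_gene, lnc_exons))
        truth.lnc_classes[lnc_tid] = (companion, gene_id)
        truth.lnc_gene_of[lnc_tid] = lnc_gene

    # intergenic features: ncRNAs and the free-standing decoys
    for ni in range(n_ncrna):
        chrom = chrom_names[ni % n_chrom]
        nlen = int(rng.integers(80, 150))
        start = _place(chrom, nlen)
        iv = GenomicInterval(chrom, start, start + nlen, "+" if rng.random() < 0.5 else "-")
        reference.add(
            TranscriptRecord(f"ncrna{ni:02d}.t1", f"ncrna{ni:02d}", iv, [iv], "ncRNA")
        )

    free_decoys = {
        "decoy_short": 150,
        "decoy_coding": None,  # ORF-bearing, length set below
        "decoy_silent": 400,
        "decoy_rfam": 350,
    }
    for di, (name, dlen) in enumerate(free_decoys.items()):
        chrom = chrom_names[di % n_chrom]
        if name == "decoy_coding":
            orf = _coding_orf(rng, 150)
            seq = "".join(_random_seq(rng, 20, gc)) + orf + "".join(_random_seq(rng, 20, gc))
        elif name == "decoy_short":
            seq = "".join(_random_seq(rng, dlen, gc))
        else:
            seq = _noncoding_seq(rng, dlen, gc)
        start = _place(chrom, len(seq))
        strand = "+" if rng.random() < 0.5 else "-"
        _write(chrom, start, seq if strand == "+" else reverse_complement(seq))
        iv = GenomicInterval(chrom, start, start + len(seq), strand)
        candidates.add(TranscriptRecord(f"{name}.t1", name, iv, [iv]))
        truth.decoys[f"{name}.t1"] = DECOY_FILTERS[name]

    hits = pd.DataFrame(
        [
            ("decoy_rfam.t1", "RF00005", "RFAM", 95.0, 1e-10, 80.0),
            ("lnc01.t1", "URS_misc", "RNAcentral", 60.0, 1e-3, 55.0),
        ],
        columns=["query_id", "subject_id", "subject_class", "identity", "evalue", "coverage"],
    )

    genome = {c: "".join(chrom_seqs[c]) for c in chrom_names}
    return SyntheticDataset(genome, reference, candidates, hits, truth)


# ---------------------------------------------------------------------------
# triplex planting
# ---------------------------------------------------------------------------

def _purine_tract(rng: np.random.Generator, length: int, min_g: float = 0.4) -> str:
    for _ in range(100):
        seq = "".join(rng.choice(["G", "A"], size=length, p=[0.55, 0.45]))
        if seq.count("G") / length >= min_g:
            return seq
    raise RuntimeError("could not draw a purine tract")


def plant_triplex_sites(
    dataset: SyntheticDataset,
    seed: int = 0,
    n_sites: int = 3,
    tract_length: int = 30,
    max_tries: int = 200,
) -> SyntheticDataset:
    """Write polypurine TTS tracts into promoters of coding genes and the
    complementary (R-motif, antiparallel) TFO tracts into plus-strand
    planted lncRNA exons.  Mutates the dataset in place and records the
    planted coordinates in its truth; returns the dataset.
    """
    rng = np.random.default_rng(seed)
    chrom_arrays = {c: np.array(list(s)) for c, s in dataset.genome.items()}

    # candidate host lncRNAs: plus strand, written-to-genome classes only
    hosts = [
        t
        for t in dataset.candidates
        if t.transcript_id in dataset.truth.lnc_classes
        and dataset.truth.lnc_classes[t.transcript_id][0] != "antisense_exonic"
        and t.strand == "+"
        and max(len(e) for e in t.exons) >= tract_length + 40
    ]
    if n_sites > 0 and not hosts:
        raise RuntimeError("no suitable plus-strand lncRNA hosts for TFO planting")

    coding = [t for t in dataset.reference if t.biotype == "coding"]
    occupied: List[Tuple[str, int, int]] = []

    def _collides(chrom: str, start: int, end: int) -> bool:
        for t in dataset.reference:
            if t.chrom == chrom and t.interval.start < end and start < t.interval.end:
                return True
        for t in dataset.candidates:
            if t.chrom == chrom and t.interval.start < end and start < t.interval.end:
                return True
        for c, s, e in occupied:
            if c == chrom and s < end and start < e:
                return True
        return False

    planted = 0
    tries = 0
    while planted < n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all triplex sites (collisions)")
        gene_t = coding[int(rng.integers(len(coding)))]
        # promoter-side intergenic spot, 100-600 bp upstream of the TSS
        off = int(rng.integers(100, 600))
        if gene_t.strand == "+":
            start = gene_t.interval.start - off - tract_length
        else:
            start = gene_t.interval.end + off
        end = start + tract_length
        if start < 0 or end > len(chrom_arrays[gene_t.chrom]):
            continue
        if _collides(gene_t.chrom, start, end):
            continue
        tts_purine = _purine_tract(rng, tract_length)
        chrom_arrays[gene_t.chrom][start:end] = list(tts_purine)
        occupied.append((gene_t.chrom, start, end))

        host = hosts[planted % len(hosts)]
        exon = max(host.exons, key=len)
        tfo_off = int(rng.integers(20, len(exon) - tract_length - 20))
        tfo = tts_purine[::-1]  # R motif: antiparallel, G<->G / A<->A
        gpos = exon.start + tfo_off
        chrom_arrays[host.chrom][gpos : gpos + tract_length] = list(tfo)
        occupied.append((host.chrom, gpos, gpos + tract_length))
        # transcript coordinate of the planted TFO
        tpos = sum(len(e) for e in host.exons if e.end <= exon.start) + tfo_off
        dataset.truth.planted_tts.append(
            {
                "chrom": gene_t.chrom,
                "tts_start": int(start),
                "tts_end": int(end),
                "gene_id": gene_t.gene_id,
                "lnc_id": host.transcript_id,
                "tfo_start": int(tpos),
                "tfo_end": int(tpos + tract_length),
            }
        )
        planted += 1

    for c in dataset.genome:
        dataset.genome[c] = "".join(chrom_arrays[c])
    return dataset


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def default_design(include_reference_chemostat: bool = True, replicates: int = 3) -> pd.DataFrame:
    """Condition/replicate design: optional high-growth chemostat plus the
    four retentostat-phase sampling points, ``replicates`` each."""
    rows = []
    conditions = (["C0.1"] if include_reference_chemostat else []) + [
        "0.025", "R3", "R6", "R10",
    ]
    for cond in conditions:
        cultivation = "C" if cond == "C0.1" else "SC"
        for r in range(1, replicates + 1):
            rows.append({"sample": f"{cond}_r{r}", "condition": cond,
                         "cultivation": cultivation, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


_GROWTH_INDEX = {"C0.1": 0.0, "0.025": 0.2, "R3": 0.6, "R6": 0.85, "R10": 1.0}


def simulate_expression(
    dataset: SyntheticDataset,
    design: Optional[pd.DataFrame] = None,
    seed: int = 0,
    dispersion: float = 0.05,
    coding_base: float = 200.0,
    lnc_base: float = 30.0,
    de_lfc: float = 2.0,
    n_de_coding: int = 10,
    rho_magnitude: float = 0.8,
) -> Dict[str, pd.DataFrame]:
    """Negative-binomial transcript counts over the design.

    Planted structure: lncRNA baselines below coding baselines; a subset
    of coding genes and lncRNAs with growth-rate-dependent means
    (log2FC = +/- ``de_lfc`` across the growth-rate range); each DE lncRNA
    correlated with its partner gene at +/- ``rho_magnitude`` via a shared
    per-sample latent factor; the 'decoy_silent' transcript silent
    everywhere.  Returns dict with counts, tpm, gene_counts, design,
    de_table; records DE truth and pair correlations in dataset.truth.
    """
    if not 0 <= rho_magnitude < 1:
        raise ValueError("|rho| must be < 1")
    if design is None:
        design = default_design()
    if design["condition"].nunique() < 2 or design["replicate"].nunique() < 2:
        raise ValueError("design needs >= 2 conditions and >= 2 replicates")
    rng = np.random.default_rng(seed)
    samples = list(design.index)
    growth = np.array([_GROWTH_INDEX.get(design.loc[s, "condition"], 0.5) for s in samples])
    zgrowth = (growth - growth.mean()) / growth.std()

    transcripts = list(dataset.reference) + list(dataset.candidates)
    tids = [t.transcript_id for t in transcripts]
    lengths = {t.transcript_id: t.spliced_length for t in transcripts}

    base_mean: Dict[str, float] = {}
    for t in transcripts:
        if t.biotype == "coding":
            base_mean[t.transcript_id] = coding_base * float(rng.lognormal(0, 0.6))
        else:
            base_mean[t.transcript_id] = lnc_base * float(rng.lognormal(0, 0.6))
    if "decoy_silent.t1" in base_mean:
        base_mean["decoy_silent.t1"] = 0.0

    # choose DE genes: alternating-sign lncRNAs plus a coding subset
    truth = dataset.truth
    truth.de_genes = {}
    truth.pair_rho = []
    lnc_ids = sorted(truth.lnc_classes)
    de_lncs = lnc_ids[: max(1, len(lnc_ids) // 2)]
    for i, lid in enumerate(de_lncs):
        truth.de_genes[truth.lnc_gene_of[lid]] = de_lfc * (1 if i % 2 == 0 else -1)
    partner_of_de = {truth.lnc_classes[lid][1] for lid in de_lncs}
    plain_coding = [
        t.gene_id
        for t in dataset.reference
        if t.biotype == "coding" and t.gene_id not in partner_of_de
    ]
    for i, gid in enumerate(plain_coding[:n_de_coding]):
        truth.de_genes[gid] = de_lfc * (1 if i % 2 == 0 else -1)

    # planted pair correlations: DE lncRNA vs its partner gene
    for i, lid in enumerate(de_lncs):
        rho = rho_magnitude * (1 if i % 2 == 0 else -1)
        truth.pair_rho.append((truth.lnc_gene_of[lid], truth.lnc_classes[lid][1], rho))
    # signed latent loading per pair member: the lncRNA follows its DE
    # direction, the gene follows it times sign(rho)
    pair_sign: Dict[str, float] = {}
    pair_id_of: Dict[str, str] = {}
    for i, (lg, cg, rho) in enumerate(truth.pair_rho):
        d_lnc = 1.0 if truth.de_genes.get(lg, 1.0) >= 0 else -1.0
        pair_id_of[lg] = f"pair{i}"
        pair_id_of[cg] = f"pair{i}"
        pair_sign[lg] = d_lnc
        pair_sign[cg] = d_lnc * float(np.sign(rho)) if rho else 0.0

    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    counts = np.zeros((len(tids), len(samples)))
    for ti, tid in enumerate(tids):
        gid = gene_of[tid]
        mu0 = base_mean[tid]
        if mu0 == 0:
            continue
        lfc = truth.de_genes.get(gid, 0.0)
        if gid in pair_id_of and pair_sign.get(gid, 0.0) != 0.0:
            # correlated-pair members: the shared growth latent IS their
            # (growth-associated) signal, scaled to yield the target rho
            sigma = np.sqrt(1.0 / mu0 + dispersion)
            amp = sigma * np.sqrt(rho_magnitude / (1 - rho_magnitude))
            log_mu = np.log(mu0) + pair_sign[gid] * amp * zgrowth - 0.5 * amp**2
        else:
            log_mu = np.log(mu0) + lfc * np.log(2) * (growth - growth.mean())
        mu = np.exp(log_mu)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts[ti] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                             columns=samples).astype(np.int64)
    tpm = compute_tpm(counts_df.astype(float), lengths)
    from .expression import aggregate_to_gene

    gene_counts = aggregate_to_gene(counts_df.astype(float), gene_of)

    de_rows = []
    for gid in sorted({gene_of[t] for t in tids}):
        lfc = truth.de_genes.get(gid, 0.0)
        de_rows.append(
            {
                "gene_id": gid,
                "contrast": "LRT_growth",
                "log2FC": lfc,
                "svalue": 1e-4 if lfc else 0.5,
                "padj": 1e-6 if lfc else 0.5,
            }
        )
    de_table = pd.DataFrame(de_rows)

    return {
        "counts": counts_df,
        "tpm": tpm,
        "gene_counts": gene_counts,
        "design": design,
        "de_table": de_table,
    }


# ---------------------------------------------------------------------------
# profile groups for clustering tests
# ---------------------------------------------------------------------------

def planted_profile_groups(
    seed: int = 0,
    n_per_group: int = 25,
    n_points: int = 4,
    noise_sd: float = 0.15,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Four well-separated temporal profile archetypes (up, down, peak,
    dip) with Gaussian noise, z-scored per row.  Returns (profiles,
    true labels)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_points)
    archetypes = np.vstack([
        t,                      # monotone up
        1 - t,                  # monotone down
        1 - np.abs(t - 0.5) * 2,  # peak
        np.abs(t - 0.5) * 2,      # dip
    ])
    rows, labels = [], []
    for g in range(4):
        for i in range(n_per_group):
            rows.append(archetypes[g] + rng.normal(0, noise_sd, n_points))
            labels.append(g)
    X = np.array(rows)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    idx = pd.Index([f"g{l}_{i}" for i, l in enumerate(labels)], name="gene_id")
    return pd.DataFrame(X, index=idx), pd.Series(labels, index=idx, name="group")
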