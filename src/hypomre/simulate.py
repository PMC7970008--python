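"""Synthetic MRE-seq data with known truth.

Emulates methylation-sensitive HpaII (C^CGG) digestion of a multi-accession
clonal genome. The genome is tiled by gene / repeat / intergenic blocks; CCGG
motifs are enriched inside genes; each accession carries rare clonal SNPs and
1-bp indels plus a per-CCGG-site methylation state (genes mostly unmethylated,
repeats mostly methylated, per-accession state flips create differentially
methylated regions). HpaII cuts between the first and second C of every
CCGG whose state is unmethylated; methylated and hemimethylated sites are
never cut (single-strand nicking is treated as negligible). Fragments inside
a size-selection window are sequenced as 300 bp paired-end reads with
substitution errors and a plateau-plus-decaying-tail quality profile;
contaminant pairs (phiX, chloroplast, mitochondrion, rRNA, repeats) are
spiked in at sub-percent fractions and labelled in the truth tables.

All randomness flows from ``SimConfig.seed`` through fixed-tag child
streams, so identical configs reproduce identical outputs byte for byte.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._io import ensure_dir, quals_to_str, write_fasta, write_fastq
from ._kmer import revcomp

GENOME_ID = "simgenome"

UNMETHYLATED = "unmethylated"
HEMIMETHYLATED = "hemimethylated"
METHYLATED = "methylated"

CONTAMINANT_CLASSES = ("phix", "repetitive", "ribosomal", "chloroplast", "mitochondrion")

#: synthetic contaminant reference lengths (bp); loosely sized like the real
#: sources (phiX ~5.4 kb, organelles tens of kb, rRNA repeat unit ~6 kb)
_CONTAMINANT_LENGTHS = {
    "phix": 5400,
    "repetitive": 10000,
    "ribosomal": 6000,
    "chloroplast": 15000,
    "mitochondrion": 9000,
}


def _default_contaminant_fractions() -> dict[str, float]:
    # sub-1% per class, repeats lowest, mirroring typical filtered libraries
    return {
        "phix": 0.005,
        "repetitive": 0.001,
        "ribosomal": 0.008,
        "chloroplast": 0.008,
        "mitochondrion": 0.005,
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults describe the default study design: a 500 kb genome, five clonal
    accessions (the last one divergent, with a multiplier on its SNP rate),
    300 bp paired-end reads and ~50k pairs per accession.
    """

    seed: int = 0
    genome_length: int = 500_000
    n_accessions: int = 5
    gene_fraction: float = 0.35
    repeat_fraction: float = 0.45
    gene_go_terms: int = 60
    ccgg_boost: float = 2.0
    p_meth_gene: float = 0.15
    p_meth_repeat: float = 0.90
    p_meth_intergenic: float = 0.50
    p_accession_flip: float = 0.05
    p_hemi: float = 0.05
    snp_rate: float = 5e-5
    indel_rate: float = 5e-6
    divergent_accession: int | None = -1
    divergent_snp_multiplier: float = 5.0
    read_length: int = 300
    frag_min: int = 100
    frag_max: int = 600
    error_rate: float = 0.002
    n_pairs: int = 50_000
    contaminant_fractions: dict[str, float] = field(default_factory=_default_contaminant_fractions)

    def validate(self) -> None:
        probs = {
            "gene_fraction": self.gene_fraction,
            "repeat_fraction": self.repeat_fraction,
            "p_meth_gene": self.p_meth_gene,
            "p_meth_repeat": self.p_meth_repeat,
            "p_meth_intergenic": self.p_meth_intergenic,
            "p_accession_flip": self.p_accession_flip,
            "p_hemi": self.p_hemi,
            "snp_rate": self.snp_rate,
            "indel_rate": self.indel_rate,
            "error_rate": self.error_rate,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name, frac in self.contaminant_fractions.items():
            if name not in CONTAMINANT_CLASSES:
                raise ValueError(f"unknown contaminant class {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"contaminant fraction {name} out of [0,1]")
        if self.gene_fraction + self.repeat_fraction > 1.0 + 1e-12:
            raise ValueError("gene_fraction + repeat_fraction must be <= 1")
        if self.frag_min >= self.frag_max:
            raise ValueError("frag_min must be < frag_max")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.genome_length < self.frag_max:
            raise ValueError("genome_length must be >= frag_max")
        if self.n_accessions < 1:
            raise ValueError("need at least one accession")
        if self.ccgg_boost < 1.0:
            raise ValueError("ccgg_boost must be >= 1")

    def accession_ids(self) -> list[str]:
        return [f"acc{i + 1:02d}" for i in range(self.n_accessions)]

    def divergent_id(self) -> str | None:
        if self.divergent_accession is None:
            return None
        return self.accession_ids()[self.divergent_accession]


@dataclass
class Feature:
    start: int
    end: int  # half-open
    cls: str  # gene | repeat | intergenic
    gene_id: str | None = None
    go_terms: tuple[str, ...] = ()


@dataclass
class ReferenceGenome:
    sequence: str
    features: list[Feature]
    ccgg_sites: np.ndarray  # sorted start positions of CCGG matches

    def site_classes(self) -> np.ndarray:
        """Feature class of each CCGG site, aligned with ccgg_sites."""
        starts = np.array([f.start for f in self.features])
        idx = np.searchsorted(starts, self.ccgg_sites, side="right") - 1
        return np.array([self.features[i].cls for i in idx])

    def gene_go(self) -> dict[str, tuple[str, ...]]:
        return {f.gene_id: f.go_terms for f in self.features if f.cls == "gene"}


@dataclass
class AccessionProfile:
    accession_id: str
    #: position -> (ref_allele, alt_allele, type); type in {snp, ins, del}.
    #: For ins, alt is the base inserted *before* the position; for del,
    #: alt is "-" and the reference base at the position is removed.
    variants: dict[int, tuple[str, str, str]]
    #: CCGG site start -> methylation state
    methylation: dict[int, str]


@dataclass
class Fragment:
    """A size-selected HpaII digest fragment of one accession.

    Coordinates are kept both on the personalized (variant-applied) sequence
    and on the reference genome, so truth tables stay comparable across
    accessions despite indel-induced coordinate shifts.
    """

    accession_id: str
    start: int
    end: int  # personalized coords, half-open
    ref_start: int
    ref_end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# reference genome


def _rng(config: SimConfig, *tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *tag])


def find_ccgg_sites(sequence: str) -> np.ndarray:
    """All CCGG motif start positions (overlap-aware scan)."""
    return np.array([m.start() for m in re.finditer("(?=CCGG)", sequence)], dtype=np.int64)


def build_reference(config: SimConfig) -> ReferenceGenome:
    """Draw the clonal reference genome: compartment tiling + CCGG planting."""
    config.validate()
    rng = _rng(config, 0)
    L = config.genome_length

    # tile the genome with feature blocks of ~1-3 kb; class probabilities are
    # the configured bp fractions (block length distribution is class-free,
    # so expected bp fractions match the draw probabilities)
    p_inter = max(0.0, 1.0 - config.gene_fraction - config.repeat_fraction)
    classes = ("gene", "repeat", "intergenic")
    probs = np.array([config.gene_fraction, config.repeat_fraction, p_inter])
    probs = probs / probs.sum()
    features: list[Feature] = []
    pos = 0
    gene_n = 0
    go_pool = [f"GO:{i + 1:07d}" for i in range(config.gene_go_terms)]
    while pos < L:
        cls = classes[rng.choice(3, p=probs)]
        size = int(rng.integers(1000, 3001))
        end = min(pos + size, L)
        if cls == "gene":
            gene_n += 1
            n_go = int(rng.integers(1, 4))
            terms = tuple(sorted(rng.choice(len(go_pool), size=n_go, replace=False)))
            features.append(
                Feature(pos, end, cls, f"gene{gene_n:04d}", tuple(go_pool[t] for t in terms))
            )
        else:
            features.append(Feature(pos, end, cls))
        pos = end

    codes = rng.integers(0, 4, size=L, dtype=np.int8)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()

    # plant extra CCGG motifs inside genes so motif density there is about
    # ccgg_boost times the random background of 1/256 per bp
    extra_rate = (config.ccgg_boost - 1.0) / 256.0
    if extra_rate > 0:
        chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        motif = np.frombuffer(b"CCGG", dtype=np.uint8)
        for f in features:
            if f.cls != "gene" or f.end - f.start < 8:
                continue
            n_extra = rng.poisson(extra_rate * (f.end - f.start))
            if n_extra == 0:
                continue
            cand = np.sort(rng.integers(f.start, f.end - 4, size=n_extra))
            last = -10
            for p in cand:
                if p - last >= 4:
                    chars[p : p + 4] = motif
                    last = p
        seq = chars.tobytes().decode()

    return ReferenceGenome(seq, features, find_ccgg_sites(seq))


# ---------------------------------------------------------------------------
# accession profiles


def derive_accessions(ref: ReferenceGenome, config: SimConfig) -> list[AccessionProfile]:
    """Plant per-accession variants and methylation states.

    The per-site baseline methylation state is drawn once (shared across
    accessions, by compartment probability) and flipped independently per
    accession with ``p_accession_flip``; a flipped-state site is what makes
    a region differentially methylated. The designated divergent accession
    gets ``divergent_snp_multiplier`` times the SNP rate.
    """
    config.validate()
    rng = _rng(config, 1)
    L = config.genome_length
    sites = ref.ccgg_sites
    site_cls = ref.site_classes()
    p_meth = {
        "gene": config.p_meth_gene,
        "repeat": config.p_meth_repeat,
        "intergenic": config.p_meth_intergenic,
    }
    baseline_meth = np.array(
        [rng.random() < p_meth[c] for c in site_cls], dtype=bool
    )

    divergent = config.divergent_id()
    profiles = []
    bases = "ACGT"
    for acc in config.accession_ids():
        snp_rate = config.snp_rate
        if acc == divergent:
            snp_rate = min(1.0, snp_rate * config.divergent_snp_multiplier)
        variants: dict[int, tuple[str, str, str]] = {}
        snp_pos = np.nonzero(rng.random(L) < snp_rate)[0]
        for p in snp_pos:
            refb = ref.sequence[p]
            alt = bases[(bases.index(refb) + int(rng.integers(1, 4))) % 4]
            variants[int(p)] = (refb, alt, "snp")
        ind_pos = np.nonzero(rng.random(L) < config.indel_rate)[0]
        for p in ind_pos:
            p = int(p)
            if p in variants:
                continue  # SNP takes precedence at a collided position
            if rng.random() < 0.5:
                variants[p] = (ref.sequence[p], bases[int(rng.integers(0, 4))], "ins")
            else:
                variants[p] = (ref.sequence[p], "-", "del")

        flip = rng.random(sites.size) < config.p_accession_flip
        meth = baseline_meth ^ flip
        hemi = rng.random(sites.size) < config.p_hemi
        states = {}
        for s, m, h in zip(sites, meth, hemi):
            if h:
                states[int(s)] = HEMIMETHYLATED
            else:
                states[int(s)] = METHYLATED if m else UNMETHYLATED
        profiles.append(AccessionProfile(acc, variants, states))
    return profiles


def personalize(
    sequence: str, variants: dict[int, tuple[str, str, str]]
) -> tuple[str, np.ndarray, np.ndarray]:
    """Apply variants to the reference sequence.

    Returns (personalized sequence, variant positions sorted, cumulative
    coordinate shift *after* each variant), so a reference coordinate r maps
    to r + shift(r) on the personalized sequence, where shift(r) is the
    cumulative indel delta of variants strictly left of r.
    """
    if not variants:
        return sequence, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pos = np.array(sorted(variants), dtype=np.int64)
    pieces = []
    deltas = []
    prev = 0
    for p in pos:
        refb, alt, typ = variants[int(p)]
        pieces.append(sequence[prev : int(p)])
        if typ == "snp":
            pieces.append(alt)
            deltas.append(0)
            prev = int(p) + 1
        elif typ == "ins":
            pieces.append(alt + sequence[int(p)])
            deltas.append(1)
            prev = int(p) + 1
        else:  # del: skip the reference base
            deltas.append(-1)
            prev = int(p) + 1
    pieces.append(sequence[prev:])
    shifts = np.cumsum(np.array(deltas, dtype=np.int64))
    return "".join(pieces), pos, shifts


def _ref_to_pers(r: int, pos: np.ndarray, shifts: np.ndarray) -> int:
    """Map a reference coordinate to personalized coordinates."""
    i = np.searchsorted(pos, r)  # variants strictly left of r (pos < r)
    return int(r) + (int(shifts[i - 1]) if i > 0 else 0)


# ---------------------------------------------------------------------------
# digestion


def cut_fragments(seq: str, cut_offsets) -> list[tuple[int, int]]:
    """Split a sequence at the given offsets into half-open intervals."""
    bounds = [0] + sorted(int(c) for c in cut_offsets if 0 < c < len(seq)) + [len(seq)]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def digest_sequence(
    seq: str,
    methylation: dict[int, str],
    frag_min: int | None = None,
    frag_max: int | None = None,
) -> list[tuple[int, int]]:
    """HpaII-digest a raw sequence given per-CCGG-site states.

    Cuts at ``site + 1`` (between the first and second C) for every site whose
    state is unmethylated; methylated and hemimethylated sites are left
    intact. Optional size selection keeps fragments within [frag_min, frag_max].
    """
    cuts = [s + 1 for s, state in methylation.items() if state == UNMETHYLATED]
    frags = cut_fragments(seq, cuts)
    if frag_min is not None:
        frags = [f for f in frags if frag_min <= f[1] - f[0] <= frag_max]
    return frags


def motif_survives(site: int, variants: dict[int, tuple[str, str, str]]) -> bool:
    """True when no variant disrupts the CCGG motif at `site`.

    A SNP or deletion anywhere in [site, site+4) destroys the motif; an
    insertion destroys it only when it falls strictly inside (it inserts a
    base *before* its position, so insertions at the motif edges are outside).
    """
    for p in range(site, site + 4):
        if p in variants:
            typ = variants[p][2]
            if typ in ("snp", "del"):
                return False
            if typ == "ins" and p > site:
                return False
    return True


def digest(
    ref: ReferenceGenome,
    profile: AccessionProfile,
    config: SimConfig,
    size_select: bool = True,
) -> list[Fragment]:
    """Digest one accession's personalized genome.

    Cut sites are the reference CCGG sites that (a) are unmethylated in this
    accession and (b) still spell CCGG after the accession's variants.
    Novel CCGG motifs created by variants carry no methylation state and are
    not cut (documented limitation).
    """
    pseq, vpos, vshift = personalize(ref.sequence, profile.variants)
    ref_cuts = [
        s + 1
        for s in map(int, ref.ccgg_sites)
        if profile.methylation.get(s) == UNMETHYLATED and motif_survives(s, profile.variants)
    ]
    pers_cuts = [_ref_to_pers(c, vpos, vshift) for c in ref_cuts]
    ref_bounds = [0] + [c for c in ref_cuts if 0 < c < len(ref.sequence)] + [len(ref.sequence)]
    pers_bounds = [0] + [c for c in pers_cuts if 0 < c < len(pseq)] + [len(pseq)]
    frags = []
    for (ps, pe), (rs, re_) in zip(
        zip(pers_bounds[:-1], pers_bounds[1:]), zip(ref_bounds[:-1], ref_bounds[1:])
    ):
        if pe <= ps:
            continue
        if size_select and not (config.frag_min <= pe - ps <= config.frag_max):
            continue
        frags.append(Fragment(profile.accession_id, ps, pe, rs, re_, pseq[ps:pe]))
    return frags


# ---------------------------------------------------------------------------
# read generation


def _quality_matrix(n: int, L: int, read_length: int, rng: np.random.Generator) -> np.ndarray:
    """Phred quality draws: high plateau with a decaying 3' tail plus jitter."""
    base = np.full(L, 38.0)
    tail = int(read_length * 0.65)
    if L > tail:
        base[tail:] = np.linspace(38.0, 31.0, L - tail)
    q = base[None, :] + rng.integers(-3, 4, size=(n, L))
    return np.clip(q, 2, 41).astype(np.uint8)


def _add_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases in a byte matrix of reads at the given per-base rate."""
    if error_rate <= 0:
        return mat
    err = rng.random(mat.shape) < error_rate
    if not err.any():
        return mat
    idx = np.nonzero(err)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    code = np.searchsorted(np.sort(lut), mat[idx])  # ACGT already sorted
    new = (code + rng.integers(1, 4, size=code.size)) % 4
    out = mat.copy()
    out[idx] = lut[new]
    return out


def _pairs_from_template(
    template: str, n: int, config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], list[str], list[str]]:
    """n read pairs from one fragment: R1 = 5' end, R2 = revcomp of 3' end."""
    L = min(len(template), config.read_length)
    r1 = np.frombuffer(template[:L].encode(), dtype=np.uint8)
    r2 = np.frombuffer(revcomp(template[-L:]).encode(), dtype=np.uint8)
    m1 = _add_errors(np.tile(r1, (n, 1)), config.error_rate, rng)
    m2 = _add_errors(np.tile(r2, (n, 1)), config.error_rate, rng)
    q1 = _quality_matrix(n, L, config.read_length, rng)
    q2 = _quality_matrix(n, L, config.read_length, rng)
    seqs1 = [m1[i].tobytes().decode() for i in range(n)]
    seqs2 = [m2[i].tobytes().decode() for i in range(n)]
    quals1 = [quals_to_str(q1[i]) for i in range(n)]
    quals2 = [quals_to_str(q2[i]) for i in range(n)]
    return seqs1, seqs2, quals1, quals2


def generate_reads(
    fragments: list[Fragment],
    config: SimConfig,
    rng: np.random.Generator,
    contaminants: dict[str, str] | None = None,
    accession_id: str = "sample",
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], pd.DataFrame]:
    """Paired reads for one accession, plus a truth table of read origins.

    Pairs are allocated uniformly over fragments; contaminant pairs are drawn
    per class with binomial counts at the configured fractions and sampled
    from random windows of the contaminant references. Output order is a
    seeded permutation of genomic + contaminant pairs.

    Returns (R1 records, R2 records, truth DataFrame with columns
    read_id / source / fragment_id).
    """
    import logging

    if not fragments:
        logging.getLogger(__name__).warning(
            "no fragments for %s: empty read set", accession_id
        )
        return [], [], pd.DataFrame(columns=["read_id", "source", "fragment_id"])

    contaminants = contaminants or {}
    n_pairs = config.n_pairs
    class_counts = {}
    for cls in CONTAMINANT_CLASSES:
        frac = config.contaminant_fractions.get(cls, 0.0)
        if frac > 0 and cls in contaminants:
            class_counts[cls] = int(rng.binomial(n_pairs, frac))
    n_genomic = n_pairs - sum(class_counts.values())

    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str, str]] = []

    frag_idx = rng.integers(0, len(fragments), size=n_genomic)
    counts = np.bincount(frag_idx, minlength=len(fragments))
    for fi, n in enumerate(counts):
        if n == 0:
            continue
        frag = fragments[fi]
        s1, s2, q1, q2 = _pairs_from_template(frag.seq, int(n), config, rng)
        fid = f"frag{fi:05d}"
        for j in range(int(n)):
            rid = f"{accession_id}:{fid}:{j}"
            r1.append((rid, s1[j], q1[j]))
            r2.append((rid, s2[j], q2[j]))
            truth_rows.append((rid, "genomic", fid))

    for cls, n in class_counts.items():
        src = contaminants[cls]
        for j in range(n):
            flen = int(rng.integers(config.frag_min, min(config.frag_max, len(src)) + 1))
            start = int(rng.integers(0, len(src) - flen + 1))
            template = src[start : start + flen]
            s1, s2, q1, q2 = _pairs_from_template(template, 1, config, rng)
            rid = f"{accession_id}:{cls}:{j}"
            r1.append((rid, s1[0], q1[0]))
            r2.append((rid, s2[0], q2[0]))
            truth_rows.append((rid, cls, "-"))

    order = rng.permutation(len(r1))
    r1 = [r1[i] for i in order]
    r2 = [r2[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=["read_id", "source", "fragment_id"])
    return r1, r2, truth


def make_contaminant_references(config: SimConfig) -> dict[str, str]:
    """Synthetic contaminant reference sequences, one per class.

    These are random stand-ins for the real screening references (phiX
    control, organelle genomes, rRNA repeats, repeat library); they are drawn
    independently of the simulated genome so truth labels are unambiguous.
    """
    rng = _rng(config, 3)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        cls: lut[rng.integers(0, 4, size=_CONTAMINANT_LENGTHS[cls])].tobytes().decode()
        for cls in CONTAMINANT_CLASSES
    }


# ---------------------------------------------------------------------------
# truth tables


def _overlaps_any(iv: tuple[int, int], sorted_starts: np.ndarray, ends: np.ndarray) -> bool:
    """Does [s,e) overlap any interval in a start-sorted interval list?"""
    s, e = iv
    i = np.searchsorted(sorted_starts, e, side="left")
    # candidate intervals start before e; check max end among them quickly
    return bool(i > 0 and (ends[:i] > s).any())


def dmr_truth(per_accession_fragments: dict[str, list[Fragment]]) -> pd.DataFrame:
    """Reference-coordinate truth for differential methylation.

    One row per distinct retained fragment interval, with the accessions that
    retain exactly that fragment (`owners`) and the accessions with *any*
    retained fragment overlapping the interval (`covered_by` — the subset in
    which the locus is unmethylated and hence sequenced).
    """
    accs = sorted(per_accession_fragments)
    per_acc_sorted = {}
    for a in accs:
        ivs = sorted((f.ref_start, f.ref_end) for f in per_accession_fragments[a])
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        per_acc_sorted[a] = (starts, ends)

    intervals: dict[tuple[int, int], set[str]] = {}
    for a in accs:
        for f in per_accession_fragments[a]:
            intervals.setdefault((f.ref_start, f.ref_end), set()).add(a)

    rows = []
    for (s, e), owners in sorted(intervals.items()):
        covered = [a for a in accs if _overlaps_any((s, e), *per_acc_sorted[a])]
        if not covered or len(covered) == len(accs):
            continue  # differential only: a strict, non-empty accession subset
        rows.append(
            {
                "chrom": GENOME_ID,
                "start": s,
                "end": e,
                "covered_by": ",".join(covered),
                "owners": ",".join(sorted(owners)),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "covered_by", "owners"])


def variants_truth(profiles: list[AccessionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for pos in sorted(p.variants):
            refb, alt, typ = p.variants[pos]
            rows.append((p.accession_id, pos, refb, alt, typ))
    return pd.DataFrame(rows, columns=["accession", "pos", "ref", "alt", "type"])


def fragments_truth(per_accession_fragments: dict[str, list[Fragment]]) -> pd.DataFrame:
    rows = []
    for acc in sorted(per_accession_fragments):
        for i, f in enumerate(per_accession_fragments[acc]):
            rows.append((acc, f"frag{i:05d}", f.ref_start, f.ref_end, f.length, f.seq))
    return pd.DataFrame(
        rows, columns=["accession", "fragment_id", "ref_start", "ref_end", "length", "seq"]
    )


# ---------------------------------------------------------------------------
# top-level run


@dataclass
class SimOutputs:
    outdir: Path
    genome_fasta: Path
    contaminants_fasta: Path
    fastq: dict[str, tuple[Path, Path]]
    truth_variants: Path
    truth_dmr: Path
    truth_fragments: Path
    truth_reads: Path
    gene_go: Path
    features: Path
    config_echo: Path


def simulate(config: SimConfig, outdir) -> SimOutputs:
    """Run the full generator and serialize every artifact to `outdir`."""
    import yaml

    config.validate()
    out = ensure_dir(outdir)
    ref = build_reference(config)
    profiles = derive_accessions(ref, config)
    contaminants = make_contaminant_references(config)

    genome_fasta = out / "genome.fasta"
    write_fasta(genome_fasta, [(GENOME_ID, ref.sequence)])
    contam_fasta = out / "contaminants.fasta"
    write_fasta(
        contam_fasta,
        [(f"{cls}_synthetic class={cls}", seq) for cls, seq in contaminants.items()],
    )

    features_path = out / "features.tsv"
    pd.DataFrame(
        [
            (f.start, f.end, f.cls, f.gene_id or "-", ",".join(f.go_terms) or "-")
            for f in ref.features
        ],
        columns=["start", "end", "class", "gene_id", "go_terms"],
    ).to_csv(features_path, sep="\t", index=False)

    gene_go_path = out / "gene_go.tsv"
    with open(gene_go_path, "w") as fh:
        fh.write("gene_id\tgo_terms\n")
        for gid, terms in ref.gene_go().items():
            fh.write(f"{gid}\t{','.join(terms)}\n")

    fastq_paths: dict[str, tuple[Path, Path]] = {}
    frag_map: dict[str, list[Fragment]] = {}
    truth_reads_frames = []
    for i, profile in enumerate(profiles):
        frags = digest(ref, profile, config)
        frag_map[profile.accession_id] = frags
        rng = _rng(config, 2, i)
        r1, r2, truth = generate_reads(frags, config, rng, contaminants, profile.accession_id)
        p1 = out / f"{profile.accession_id}_R1.fastq"
        p2 = out / f"{profile.accession_id}_R2.fastq"
        write_fastq(p1, r1)
        write_fastq(p2, r2)
        fastq_paths[profile.accession_id] = (p1, p2)
        truth_reads_frames.append(truth[truth["source"] != "genomic"])

    tv = out / "truth_variants.tsv"
    variants_truth(profiles).to_csv(tv, sep="\t", index=False)
    td = out / "truth_dmr.bed"
    dmr_truth(frag_map).to_csv(td, sep="\t", index=False, header=False)
    tf = out / "truth_fragments.tsv"
    fragments_truth(frag_map).to_csv(tf, sep="\t", index=False)
    tr = out / "truth_reads.tsv"
    # only non-genomic reads are listed; absence means genomic/clean
    pd.concat(truth_reads_frames, ignore_index=True).to_csv(tr, sep="\t", index=False)

    cfg_echo = out / "sim_config.yaml"
    with open(cfg_echo, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    return SimOutputs(
        out, genome_fasta, contam_fasta, fastq_paths, tv, td, tf, tr,
        gene_go_path, features_path, cfg_echo,
    )
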