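"""Allele validation from clone sequences and per-animal genotyping.

The evidence rule is the clone-study standard: an allele is validated by at
least two clones with identical sequences either from different animals or
from independent PCRs of one animal. Error-containing near-duplicates are
never merged into alleles — the evidence rule alone filters sequencing
errors, because two independent clones almost never share the same error.
Alternatively spliced clones are excluded from allele calling; only clones
with the constitutive exon structure contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import GeneModel, TranscriptSeq
from .splicing import AlignmentError, GeneIndex, classify_transcript

__all__ = [
    "ContaminationError",
    "AlleleCall",
    "Genotype",
    "GeneAssigner",
    "cluster_clones",
    "call_alleles",
    "genotype_animals",
    "call_pipeline",
]

log = logging.getLogger(__name__)


class ContaminationError(ValueError):
    """More than two validated alleles for one animal and gene."""


@dataclass(frozen=True)
class AlleleCall:
    gene_id: str
    allele_name: str
    sequence: str
    support: tuple  # of (animal, pcr_batch, clone_id)
    status: str  # 'validated' | 'singleton'

    def __post_init__(self):
        if self.status == "validated":
            animals = {s[0] for s in self.support}
            batches = {s[1] for s in self.support}
            if len(self.support) < 2 or (len(animals) < 2 and len(batches) < 2):
                raise ValueError(
                    f"{self.allele_name}: validated without two clones from "
                    "different animals or independent PCRs"
                )


@dataclass(frozen=True)
class Genotype:
    animal: str
    gene_id: str
    alleles: frozenset

    def __post_init__(self):
        if len(self.alleles) > 2:
            raise ValueError("a diploid genotype holds at most two alleles")


class GeneAssigner:
    """Assign clones to genes by unique 31-mer anchor vote.

    A k-mer votes for a gene only if it occurs in exactly one gene's genomic
    sequence. Clones with tied or empty votes stay unassigned (logged).
    """

    def __init__(self, models: dict[str, GeneModel], k: int = 31):
        self.k = k
        index: dict[str, str] = {}
        shared = set()
        for gid, m in models.items():
            seen_here = set()
            for pos in range(len(m.genomic_seq) - k + 1):
                km = m.genomic_seq[pos : pos + k]
                if km in seen_here:
                    continue
                seen_here.add(km)
                if km in index and index[km] != gid:
                    shared.add(km)
                index[km] = gid
        for km in shared:
            index.pop(km, None)
        self.index = index

    def assign(self, clone: TranscriptSeq) -> str | None:
        votes: dict[str, int] = {}
        s = clone.seq
        for i in range(len(s) - self.k + 1):
            gid = self.index.get(s[i : i + self.k])
            if gid:
                votes[gid] = votes.get(gid, 0) + 1
        if not votes:
            log.warning("clone %s: no gene-specific anchors", clone.clone_id)
            return None
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            log.warning("clone %s: ambiguous gene assignment", clone.clone_id)
            return None
        return ranked[0][0]


def cluster_clones(clones, models: dict[str, GeneModel], assigner: GeneAssigner | None = None):
    """Group constitutive-structure clones by exact sequence.

    Returns ``(clusters, meta)`` where ``clusters`` maps ``(gene, sequence)``
    to a support list of ``(animal, pcr_batch, clone_id)`` in input order, and
    ``meta`` records per-clone outcomes: gene assignment, AS exclusion,
    alignment failures.
    """
    assigner = assigner or GeneAssigner(models)
    indexes = {gid: GeneIndex(m) for gid, m in models.items()}
    clusters: dict[tuple, list] = {}
    meta = {"as_excluded": [], "unassigned": [], "unalignable": [], "gene_of": {}}
    for clone in clones:
        gid = assigner.assign(clone)
        if gid is None:
            meta["unassigned"].append(clone.clone_id)
            continue
        meta["gene_of"][clone.clone_id] = gid
        try:
            _, events = classify_transcript(clone, indexes[gid])
        except AlignmentError as exc:
            log.warning("clone %s unalignable: %s", clone.clone_id, exc)
            meta["unalignable"].append(clone.clone_id)
            continue
        if events:
            meta["as_excluded"].append(clone.clone_id)
            continue
        clusters.setdefault((gid, clone.seq), []).append(
            (clone.source_animal, clone.pcr_batch, clone.clone_id)
        )
    return clusters, meta


def call_alleles(clusters) -> list[AlleleCall]:
    """Apply the evidence rule to exact-sequence clusters.

    Validated alleles receive serial names ``gene*NN`` in first-observation
    order (lexicographic sequence as tie-break); singletons are retained for
    reporting but never genotyped.
    """
    order: dict[tuple, int] = {}
    for i, key in enumerate(clusters):
        order[key] = i
    calls: list[AlleleCall] = []
    serial: dict[str, int] = {}
    for key in sorted(clusters, key=lambda kk: (order[kk], kk[1])):
        gid, seq = key
        support = tuple(clusters[key])
        animals = {s[0] for s in support}
        batches = {s[1] for s in support}
        validated = len(support) >= 2 and (len(animals) >= 2 or len(batches) >= 2)
        if validated:
            serial[gid] = serial.get(gid, 0) + 1
            name = f"{gid}*{serial[gid]:02d}"
            status = "validated"
        else:
            name = f"{gid}:singleton:{support[0][2]}"
            status = "singleton"
        calls.append(AlleleCall(gid, name, seq, support, status))
    return calls


def genotype_animals(calls) -> list[Genotype]:
    """Per animal and gene, the set of validated alleles its clones support.

    More than two validated alleles for one animal/gene indicates
    contamination or paralog collapse and raises, never silently truncates.
    """
    per: dict[tuple, set] = {}
    for call in calls:
        if call.status != "validated":
            continue
        for animal, _, _ in call.support:
            per.setdefault((animal, call.gene_id), set()).add(call.allele_name)
    out = []
    for (animal, gid), names in sorted(per.items()):
        if len(names) > 2:
            raise ContaminationError(
                f"{animal}/{gid}: {len(names)} validated alleles {sorted(names)}"
            )
        out.append(Genotype(animal, gid, frozenset(names)))
    return out


def call_pipeline(clones, models):
    """cluster → call → genotype in one step; returns (calls, genotypes, meta)."""
    clusters, meta = cluster_clones(clones, models)
    calls = call_alleles(clusters)
    genotypes = genotype_animals(calls)
    return calls, genotypes, meta
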