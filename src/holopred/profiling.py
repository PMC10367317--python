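"""Reduced-representation metagenome profiling.

Turns demultiplexed per-sample reads into count tables, by two routes:

* Reference-free (RF): each feature is a "tag" — the first 65 bases of a
  read that starts at the restriction-site remnant (TGCAG for PstI).
  Tags observed in at least 25% of a group's samples are retained.
* Reference-based (RB): precomputed tabular alignment hits are resolved
  to a taxon per read by a MEGAN-style lowest-common-ancestor rule, and
  reads assigned at the genus level are counted against a fixed genus
  list.

Read QC is a minimal quality trimmer: 3'-end partial-sum trimming at a
Phred threshold (the algorithm popularised by BWA and used by cutadapt's
``-q``), followed by a minimum-length filter; samples with fewer than
100,000 reads after QC are flagged as failed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ReadBatch",
    "TagCatalog",
    "qc_reads",
    "flag_failed_samples",
    "extract_tags",
    "build_tag_table",
    "read_taxonomy",
    "assign_lca",
    "genus_profile",
    "DEFAULT_REMNANT",
    "TAG_LENGTH",
]

DEFAULT_REMNANT = "TGCAG"  # PstI CTGCA^G leaves TGCAG at the read start
TAG_LENGTH = 65
PHRED_OFFSET = 33


@dataclass
class ReadBatch:
    """Reads for one sample: (sequence, Phred quality string) pairs."""

    sample_id: str
    records: list  # list of (seq, qual) tuples

    def __post_init__(self):
        for i, (seq, qual) in enumerate(self.records):
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {i} of sample {self.sample_id}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TagCatalog:
    """Retained tags for a group, with per-tag sample prevalence."""

    tags: list
    prevalence: dict
    group_id: str
    tag_length: int = TAG_LENGTH
    remnant: str = DEFAULT_REMNANT


def _trim_position(qual: str, threshold: int) -> int:
    """Partial-sum 3' trim point: keep qual[:k].

    Walking from the 3' end, accumulate (threshold - q); the read is cut
    where that running sum is maximal (and positive).  Equivalent to
    BWA's -q / cutadapt's quality trimming.
    """
    best = 0
    s = 0
    cut = len(qual)
    for i in range(len(qual) - 1, -1, -1):
        s += threshold - (ord(qual[i]) - PHRED_OFFSET)
        if s > best:
            best = s
            cut = i
    return cut


def qc_reads(
    batch: ReadBatch, phred_threshold: int = 20, min_length: int = 40
) -> ReadBatch:
    """Quality-trim reads from the 3' end and drop short survivors.

    Reads shorter than ``min_length`` after trimming are removed; input
    order is preserved.
    """
    kept = []
    for seq, qual in batch.records:
        k = _trim_position(qual, phred_threshold)
        if k >= min_length:
            kept.append((seq[:k], qual[:k]))
    return ReadBatch(sample_id=batch.sample_id, records=kept)


def flag_failed_samples(read_counts: dict, min_reads: int = 100_000) -> dict:
    """Per-sample pass/fail: fail iff post-QC read count < min_reads."""
    out = {}
    for sample, n in read_counts.items():
        if n < 0:
            raise ValueError(f"negative read count for sample {sample!r}")
        out[sample] = n >= min_reads
    return out


def extract_tags(
    batch: ReadBatch,
    tag_length: int = TAG_LENGTH,
    remnant: str = DEFAULT_REMNANT,
) -> tuple[Counter, dict]:
    """Count fixed-length cut-site tags in a QC'd read batch.

    A read contributes the tag ``read[:tag_length]`` iff it begins with
    the restriction-site remnant, is at least ``tag_length`` long, and
    the tag contains no ambiguous base (N).  Everything else is skipped
    and tallied in the returned skip report.
    """
    counts: Counter = Counter()
    skipped = {"no_remnant": 0, "too_short": 0, "ambiguous": 0}
    for seq, _qual in batch.records:
        if not seq.startswith(remnant):
            skipped["no_remnant"] += 1
        elif len(seq) < tag_length:
            skipped["too_short"] += 1
        else:
            tag = seq[:tag_length]
            if "N" in tag:
                skipped["ambiguous"] += 1
            else:
                counts[tag] += 1
    return counts, skipped


def build_tag_table(
    per_sample_counts: dict,
    group_id: str,
    prevalence_threshold: float = 0.25,
    tag_length: int = TAG_LENGTH,
    remnant: str = DEFAULT_REMNANT,
) -> tuple[pd.DataFrame, TagCatalog]:
    """Assemble a samples x tags count table with a prevalence filter.

    Tags with a nonzero count in at least ``prevalence_threshold`` of the
    group's samples (inclusive boundary) are retained; columns are sorted
    lexicographically so the table is byte-reproducible.

    Parameters
    ----------
    per_sample_counts : dict
        sample_id -> Counter of tag counts (from :func:`extract_tags`).
    group_id : str
        The profiling group the samples belong to (tags are defined
        within group).
    """
    if len(per_sample_counts) < 2:
        raise ValueError("prevalence filtering needs at least 2 samples")
    samples = list(per_sample_counts)
    n = len(samples)
    present: Counter = Counter()
    for c in per_sample_counts.values():
        present.update(tag for tag, k in c.items() if k > 0)
    kept = sorted(t for t, k in present.items() if k / n >= prevalence_threshold)
    table = pd.DataFrame(
        [[per_sample_counts[s].get(t, 0) for t in kept] for s in samples],
        index=samples,
        columns=kept,
        dtype=int,
    )
    catalog = TagCatalog(
        tags=kept,
        prevalence={t: present[t] / n for t in kept},
        group_id=group_id,
        tag_length=tag_length,
        remnant=remnant,
    )
    return table, catalog


def read_taxonomy(path) -> dict:
    """Read a genome_id -> lineage map from TSV (id, semicolon lineage)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["genome_id", "lineage"])
    return {
        str(r.genome_id): tuple(x.strip() for x in str(r.lineage).split(";"))
        for r in df.itertuples()
    }


def assign_lca(
    hits: pd.DataFrame,
    taxonomy: dict,
    min_bitscore: float = 50.0,
    top_percent: float = 0.10,
) -> dict:
    """MEGAN-style LCA assignment per read from tabular alignment hits.

    For each read: discard hits scoring below ``min_bitscore`` and hits
    scoring below ``(1 - top_percent)`` of the read's best bit-score;
    assign the lowest common ancestor (longest common lineage prefix) of
    the surviving subject genomes.  Reads with no surviving hit map to
    ``None``.

    Parameters
    ----------
    hits : DataFrame
        Columns ``read_id``, ``subject_genome_id``, ``bitscore``
        (``evalue`` optional, unused).
    taxonomy : dict
        genome_id -> lineage tuple (root ... genus, species).
    """
    unknown = set(hits["subject_genome_id"].astype(str)) - set(taxonomy)
    if unknown:
        raise KeyError(f"genome id(s) missing from taxonomy: {sorted(unknown)}")
    out = {}
    for read_id, grp in hits.groupby("read_id", sort=False):
        scores = grp["bitscore"].to_numpy(dtype=float)
        keep = scores >= min_bitscore
        if keep.any():
            keep &= scores >= (1.0 - top_percent) * scores[keep].max()
        if not keep.any():
            out[read_id] = None
            continue
        lineages = [
            taxonomy[str(g)]
            for g in grp.loc[keep, "subject_genome_id"]
        ]
        lca = lineages[0]
        for lin in lineages[1:]:
            k = 0
            while k < min(len(lca), len(lin)) and lca[k] == lin[k]:
                k += 1
            lca = lca[:k]
        out[read_id] = lca if lca else None
    return out


def genus_profile(
    assignments: dict,
    genus_list: list,
    genus_rank: int = 5,
) -> tuple[pd.Series, dict]:
    """Count reads assigned exactly at the genus level against a genus list.

    ``genus_rank`` is the 0-based position of genus within the lineage
    (5 in a domain/phylum/class/order/family/genus/species lineage).
    Reads assigned above or below genus, to an unlisted genus, or not at
    all are excluded from the profile but tallied.

    Returns
    -------
    (counts, tally) : per-genus counts (Series over ``genus_list``) and a
    dict of excluded-read categories.
    """
    if not genus_list:
        raise ValueError("genus_list must be non-empty")
    counts = pd.Series(0, index=list(genus_list), dtype=int)
    tally = {"unassigned": 0, "above_genus": 0, "below_genus": 0,
             "unlisted_genus": 0}
    for lineage in assignments.values():
        if lineage is None:
            tally["unassigned"] += 1
        elif len(lineage) <= genus_rank:
            tally["above_genus"] += 1
        elif len(lineage) > genus_rank + 1:
            tally["below_genus"] += 1
        else:
            genus = lineage[genus_rank]
            if genus in counts.index:
                counts[genus] += 1
            else:
                tally["unlisted_genus"] += 1
    return counts, tally
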