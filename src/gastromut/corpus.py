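"""Labelled benchmark-corpus construction.

The benchmark dataset ``D = D+ ∪ D-`` pairs carcinoma-mutated gene sequences
(positive class, label 1) with normal reference sequences (negative class,
label 0).  Positives are produced by splicing mutation records (substitution,
insertion, deletion; 1-based coordinates) into reference genes, one mutated
sequence per record.  Both classes are deduplicated at 100% identity
(exact-string removal, the behaviour of CD-HIT at a 1.0 similarity threshold)
and the majority class is down-sampled so the corpus is balanced.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, ParseError, ValidationError

ALLOWED_SYMBOLS = frozenset("ACGTN")
ALLELE_SYMBOLS = frozenset("ACGT")

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
MUTATION_KINDS = (SUBSTITUTION, INSERTION, DELETION)


@dataclass(frozen=True)
class ReferenceGene:
    """A normal gene sequence: negative sample and mutation substrate."""

    gene_id: str
    symbol: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(seq) - ALLOWED_SYMBOLS
        if bad:
            raise ValidationError(
                f"gene {self.gene_id!r}: illegal symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MutationRecord:
    """One edit at a 1-based position of a named gene."""

    gene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    kind: str
    record_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.kind not in MUTATION_KINDS:
            raise ValidationError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise ValidationError(
                f"mutation {self.record_id or self.gene_id}: position must be >= 1"
            )
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if set(allele) - ALLELE_SYMBOLS:
                raise ValidationError(
                    f"mutation {self.record_id or self.gene_id}: "
                    f"illegal {name} allele {allele!r}"
                )
        ok = {
            SUBSTITUTION: len(self.ref_allele) == len(self.alt_allele) >= 1,
            INSERTION: len(self.ref_allele) == 0 and len(self.alt_allele) >= 1,
            DELETION: len(self.ref_allele) >= 1 and len(self.alt_allele) == 0,
        }[self.kind]
        if not ok:
            raise ValidationError(
                f"mutation {self.record_id or self.gene_id}: allele lengths "
                f"({len(self.ref_allele)}, {len(self.alt_allele)}) invalid for {self.kind}"
            )


@dataclass(frozen=True)
class LabeledSequence:
    """A sequence with a binary class label (1 = mutated, 0 = normal)."""

    sample_id: str
    sequence: str
    label: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(f"sample {self.sample_id!r}: label must be 0 or 1")
        if not self.sequence:
            raise ValidationError(f"sample {self.sample_id!r}: empty sequence")


def read_fasta(path: str | Path) -> list[ReferenceGene]:
    """Read reference genes from a FASTA file (sequences upper-cased).

    Raises :class:`ParseError` naming the line number on the first illegal
    character or malformed header.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    genes: list[ReferenceGene] = []
    for record in SeqIO.parse(str(path), "fasta"):
        symbol = record.description.split()[1] if " " in record.description.strip() else record.id
        genes.append(ReferenceGene(gene_id=record.id, symbol=symbol, sequence=str(record.seq).upper()))
    return genes


def _validate_fasta_lines(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            else:
                if not seen_header:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                bad = set(line.upper()) - ALLOWED_SYMBOLS
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
                    )


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read mutation records from a header-bearing TSV/CSV.

    Expected columns: gene_id, position, ref, alt, kind.  The delimiter is
    sniffed from the header line (tab or comma).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline()
        delim = "\t" if "\t" in header else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"gene_id", "position", "ref", "alt", "kind"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: mutation table must have columns {sorted(required)}"
            )
        records = []
        for i, row in enumerate(reader):
            try:
                records.append(
                    MutationRecord(
                        gene_id=row["gene_id"],
                        position=int(row["position"]),
                        ref_allele=row["ref"].strip(),
                        alt_allele=row["alt"].strip(),
                        kind=row["kind"].strip().lower(),
                        record_id=row.get("record_id") or f"{path.name}:{i}",
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def apply_mutation(gene: ReferenceGene, mut: MutationRecord) -> str:
    """Splice one mutation into a reference sequence and return the result.

    Coordinates are 1-based and inclusive; an insertion lands *after* the
    stated position.  For substitutions and deletions the reference slice is
    checked against the record's ref allele.
    """
    if mut.gene_id != gene.gene_id:
        raise ValidationError(
            f"mutation targets gene {mut.gene_id!r}, got {gene.gene_id!r}"
        )
    seq, n = gene.sequence, len(gene.sequence)
    if mut.kind == INSERTION:
        # position 0 would mean "before the first base"; we require >= 1 so the
        # insertion point is anchored to an existing base.
        if mut.position > n:
            raise ValidationError(
                f"mutation {mut.record_id or mut.gene_id}: insertion position "
                f"{mut.position} beyond sequence length {n}"
            )
        return seq[: mut.position] + mut.alt_allele + seq[mut.position :]
    start = mut.position - 1
    end = start + len(mut.ref_allele)
    if mut.position > n or end > n:
        raise ValidationError(
            f"mutation {mut.record_id or mut.gene_id}: positions "
            f"{mut.position}..{end} beyond sequence length {n}"
        )
    observed = seq[start:end]
    if observed != mut.ref_allele:
        raise ValidationError(
            f"mutation {mut.record_id or mut.gene_id}: reference mismatch at "
            f"position {mut.position}: expected {mut.ref_allele!r}, observed {observed!r}"
        )
    return seq[:start] + mut.alt_allele + seq[end:]


def deduplicate(seqs: Sequence[LabeledSequence]) -> list[LabeledSequence]:
    """Remove exact-duplicate sequences, keeping the first occurrence.

    Equivalent to CD-HIT clustering at a 100% similarity ratio over the full
    length: only byte-identical strings collapse.  Order is preserved.
    """
    seen: set[str] = set()
    out = []
    for s in seqs:
        if s.sequence not in seen:
            seen.add(s.sequence)
            out.append(s)
    return out


def balance(
    pos: Sequence[LabeledSequence],
    neg: Sequence[LabeledSequence],
    seed: int,
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Down-sample the majority class to the minority size, uniformly at random."""
    if not pos or not neg:
        raise ConfigurationError(
            f"both classes must be non-empty (got {len(pos)} positives, "
            f"{len(neg)} negatives)"
        )
    rng = np.random.default_rng(seed)
    target = min(len(pos), len(neg))

    def down(items: Sequence[LabeledSequence]) -> list[LabeledSequence]:
        if len(items) == target:
            return list(items)
        keep = rng.choice(len(items), size=target, replace=False)
        keep.sort()  # preserve relative order
        return [items[i] for i in keep]

    # sample the majority class only; a single rng keeps the draw deterministic
    if len(pos) >= len(neg):
        return down(pos), list(neg)
    return list(pos), down(neg)


def build_corpus(
    refs: Sequence[ReferenceGene],
    muts: Sequence[MutationRecord],
    seed: int,
    transform_positive: Callable[[str, np.random.Generator], str] | None = None,
) -> list[LabeledSequence]:
    """Build the balanced labelled corpus from references and mutation records.

    One mutated sequence is emitted per mutation record (label 1); every
    reference contributes one normal sequence (label 0).  Both classes are
    deduplicated independently, then balanced with :func:`balance`.

    ``transform_positive`` optionally rewrites each mutated sequence before
    deduplication (used by the synthetic-data module to implant a
    separability motif).
    """
    by_id = {g.gene_id: g for g in refs}
    rng = np.random.default_rng(seed)
    positives: list[LabeledSequence] = []
    for i, mut in enumerate(muts):
        gene = by_id.get(mut.gene_id)
        if gene is None:
            raise ValidationError(
                f"mutation record {mut.record_id or i} references unknown gene "
                f"{mut.gene_id!r}"
            )
        try:
            mutated = apply_mutation(gene, mut)
        except ValidationError as exc:
            raise ValidationError(f"record {mut.record_id or i}: {exc}") from exc
        if transform_positive is not None:
            mutated = transform_positive(mutated, rng)
        positives.append(
            LabeledSequence(
                sample_id=f"pos_{i:05d}",
                sequence=mutated,
                label=1,
                provenance=f"{mut.gene_id}|{mut.record_id or i}",
            )
        )
    negatives = [
        LabeledSequence(
            sample_id=f"neg_{i:05d}", sequence=g.sequence, label=0, provenance=g.gene_id
        )
        for i, g in enumerate(refs)
    ]
    pos = deduplicate(positives)
    neg = deduplicate(negatives)
    pos, neg = balance(pos, neg, seed=seed)
    return pos + neg


def write_labeled_fasta(corpus: Iterable[LabeledSequence], path: str | Path) -> None:
    """Write the corpus as labelled FASTA (label encoded as ``|label=0/1``)."""
    with open(path, "w") as fh:
        for s in corpus:
            fh.write(f">{s.sample_id}|label={s.label} {s.provenance}\n{s.sequence}\n")


def read_labeled_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read a corpus written by :func:`write_labeled_fasta`."""
    out = []
    for record in SeqIO.parse(str(Path(path)), "fasta"):
        rid = record.id
        if "|label=" not in rid:
            raise ParseError(f"{path}: header {rid!r} lacks a |label= tag")
        sample_id, label_part = rid.rsplit("|label=", 1)
        prov = record.description.split(" ", 1)[1] if " " in record.description else ""
        out.append(
            LabeledSequence(
                sample_id=sample_id,
                sequence=str(record.seq).upper(),
                label=int(label_part),
                provenance=prov,
            )
        )
    return out


def write_manifest(
    corpus: Iterable[LabeledSequence], path: str | Path, provenance: str | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(provenance if provenance.endswith("\n") else provenance + "\n")
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label", "length", "provenance"])
        for s in corpus:
            writer.writerow([s.sample_id, s.label, len(s.sequence), s.provenance])
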