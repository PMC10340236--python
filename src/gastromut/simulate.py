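"""Synthetic reference genes and mutation catalogues.

Emulates the statistical shape of the gastric-carcinoma benchmark — 61
driver genes, per-gene somatic mutation counts heavily skewed over 3-293,
a substitution-dominated mutation-type mix — so the whole pipeline is
testable without any download.  Sequences are i.i.d. uniform-composition
DNA; per-gene mutation counts are log-uniform integers, mimicking the
observed heavy skew (median near 18, maximum 293) without asserting a
distribution the data do not pin down.

An optional *separability motif* can be implanted into every positive
sequence.  This is purely a testing device: it guarantees learnable signal
so classifier-recovery tests have a known answer.  It makes no biological
claim about mutation signatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    LabeledSequence,
    MutationRecord,
    ReferenceGene,
    build_corpus,
)
from .errors import ConfigurationError

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 61
    length_range: tuple[int, int] = (300, 3000)
    mutation_count_range: tuple[int, int] = (3, 293)
    type_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # sub / ins / del
    separability_motif: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("need at least one gene")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ConfigurationError("lengths must be >= 10 and ordered")
        clo, chi = self.mutation_count_range
        if clo < 1 or chi < clo:
            raise ConfigurationError("mutation counts must be >= 1 and ordered")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ConfigurationError("mutation type mix must sum to 1")
        if self.separability_motif is not None:
            motif = self.separability_motif.upper()
            if not motif or set(motif) - set("ACGT"):
                raise ConfigurationError("motif must be a non-empty ACGT string")
            if len(motif) >= lo:
                raise ConfigurationError("motif longer than the shortest gene")


def simulate_references(cfg: SimulationConfig) -> list[ReferenceGene]:
    """Draw ``cfg.n_genes`` uniform-composition genes within the length range."""
    rng = np.random.default_rng(cfg.seed)
    genes = []
    for i in range(cfg.n_genes):
        n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = "".join(NUCLEOTIDES[rng.integers(0, 4, size=n)])
        genes.append(ReferenceGene(gene_id=f"gene_{i:04d}", symbol=f"SYN{i:04d}", sequence=seq))
    return genes


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))))


def simulate_mutations(refs: list[ReferenceGene], cfg: SimulationConfig) -> list[MutationRecord]:
    """Per-gene mutation catalogues; every record applies cleanly by construction."""
    if not refs:
        raise ConfigurationError("need at least one reference gene")
    rng = np.random.default_rng(cfg.seed + 1)
    kinds = (SUBSTITUTION, INSERTION, DELETION)
    records = []
    for gene in refs:
        count = _log_uniform_int(rng, *cfg.mutation_count_range)
        n = len(gene.sequence)
        for j in range(count):
            kind = kinds[rng.choice(3, p=cfg.type_mix)]
            pos = int(rng.integers(1, n + 1))
            ref_base = gene.sequence[pos - 1]
            if kind == SUBSTITUTION:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                ref, alt_allele = ref_base, alt
            elif kind == INSERTION:
                ref, alt_allele = "", "".join(NUCLEOTIDES[rng.integers(0, 4, size=int(rng.integers(1, 4)))])
            else:  # deletion of 1-3 bases, clipped to the sequence end
                span = min(int(rng.integers(1, 4)), n - pos + 1)
                ref, alt_allele = gene.sequence[pos - 1 : pos - 1 + span], ""
            records.append(
                MutationRecord(
                    gene_id=gene.gene_id,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt_allele,
                    kind=kind,
                    record_id=f"{gene.gene_id}_m{j:04d}",
                )
            )
    return records


def _motif_implanter(motif: str):
    def implant(seq: str, rng: np.random.Generator) -> str:
        start = int(rng.integers(0, len(seq) - len(motif) + 1))
        return seq[:start] + motif + seq[start + len(motif) :]

    return implant


def simulate_corpus(cfg: SimulationConfig) -> tuple[list[LabeledSequence], dict]:
    """Full synthetic benchmark: references → mutations → balanced corpus.

    Returns the corpus and a ground-truth manifest (gene lengths, mutation
    counts, motif, seeds).  When a separability motif is configured it is
    implanted at a random position of every positive sequence.
    """
    refs = simulate_references(cfg)
    muts = simulate_mutations(refs, cfg)
    transform = _motif_implanter(cfg.separability_motif.upper()) if cfg.separability_motif else None
    corpus = build_corpus(refs, muts, seed=cfg.seed + 2, transform_positive=transform)
    manifest = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "n_mutation_records": len(muts),
        "n_positive": sum(1 for s in corpus if s.label == 1),
        "n_negative": sum(1 for s in corpus if s.label == 0),
        "separability_motif": cfg.separability_motif,
        "gene_lengths": {g.gene_id: len(g.sequence) for g in refs},
        "mutations_per_gene": {
            g.gene_id: sum(1 for m in muts if m.gene_id == g.gene_id) for g in refs
        },
    }
    return corpus, manifest


def write_manifest_json(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))
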