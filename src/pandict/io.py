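"""Reading gene sets and writing pan-genome result tables.

Genomes are handled as bags of amino-acid gene sequences.  Two input layouts
are supported: one protein multi-FASTA per genome, and a single 4-column
tab-separated gene table (genome_id, gene_id, product, sequence).  Outputs are
a per-member family table, a presence/absence matrix and a genome-count
summary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: the 20 standard amino acids; anything else is masked to 'X' and never
#: contributes a k-mer.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "X"

_NONSTANDARD = set("BZUJO*")


class ParseError(ValueError):
    """Raised for malformed FASTA / gene-table input."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase, strip a trailing stop '*', and mask non-standard residues.

    Residues outside the 20-letter alphabet (B, Z, U, J, O and any other
    unexpected character) become 'X'; k-mers covering an 'X' are later
    discarded by the index, exactly like k-mers crossing a gene boundary.
    """
    s = seq.upper().strip()
    if s.endswith("*"):
        s = s[:-1]
    out = []
    for ch in s:
        if ch in STANDARD_AA:
            out.append(ch)
        else:
            out.append(AMBIGUOUS)
    return "".join(out)


@dataclass(frozen=True)
class Gene:
    """A single gene: an amino-acid string with genome membership."""

    gene_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"gene {self.gene_id!r} has empty sequence")
        bad = set(self.sequence) - set(STANDARD_AA) - {AMBIGUOUS}
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r} contains invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class GeneSet:
    """The gene collection of one genome.

    ``genetic_length`` is the sum of the gene lengths (the ⟨G⟩ of the word
    length formula); gene order is input order, but all tie-breaking
    downstream uses (genome_id, gene_id) lexicographic order.
    """

    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise ValueError(
                    f"gene {g.gene_id!r} carries genome {g.genome_id!r}, "
                    f"expected {self.genome_id!r}"
                )
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r} in {self.genome_id!r}")
            seen.add(g.gene_id)

    @property
    def genetic_length(self) -> int:
        return sum(g.length for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class FamilyAssignment:
    """One gene family: its members and its pan-genome category."""

    family_id: int
    members: frozenset[tuple[str, str]]  # (genome_id, gene_id)
    category: str  # core | dispensable | singleton
    genome_count: int

    @staticmethod
    def from_members(
        family_id: int, members: Iterable[tuple[str, str]], n_genomes: int
    ) -> "FamilyAssignment":
        members = frozenset(members)
        if not members:
            raise ValueError("family with no members")
        genome_count = len({g for g, _ in members})
        if len(members) == 1:
            category = "singleton"
        elif genome_count == n_genomes:
            category = "core"
        else:
            category = "dispensable"
        return FamilyAssignment(family_id, members, category, genome_count)


def read_proteome_fasta(path: str | os.PathLike, genome_id: str | None = None) -> GeneSet:
    """Read one genome's protein multi-FASTA.

    The token before the first whitespace of each header becomes the gene id.
    Sequences are uppercased, a trailing '*' stop is stripped, and
    non-standard residues are masked to 'X'.
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    genes: list[Gene] = []
    seen: set[str] = set()
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    for rec in records:
        seq = sanitize_sequence(str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genes.append(Gene(gene_id=rec.id, genome_id=genome_id, sequence=seq))
    return GeneSet(genome_id=genome_id, genes=genes)


def read_gene_table(path: str | os.PathLike) -> list[GeneSet]:
    """Read the 4-column gene table: genome_id, gene_id, product, sequence.

    Tab-separated, no header; one GeneSet per distinct genome_id in
    first-appearance order.
    """
    per_genome: dict[str, list[Gene]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            genome_id, gene_id, _product, sequence = fields
            key = (genome_id, gene_id)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene {key}")
            seen.add(key)
            seq = sanitize_sequence(sequence)
            if not seq:
                raise ParseError(f"{path}:{lineno}: empty sequence for {key}")
            per_genome.setdefault(genome_id, []).append(
                Gene(gene_id=gene_id, genome_id=genome_id, sequence=seq)
            )
    if not per_genome:
        raise ParseError(f"{path}: empty gene table")
    return [GeneSet(genome_id=g, genes=genes) for g, genes in per_genome.items()]


def write_gene_table(genesets: Sequence[GeneSet], path: str | os.PathLike) -> None:
    """Write gene sets in the 4-column tab-separated layout."""
    with open(path, "w") as fh:
        for gs in genesets:
            for g in gs:
                fh.write(f"{gs.genome_id}\t{g.gene_id}\thypothetical protein\t{g.sequence}\n")


def write_families(families: Sequence[FamilyAssignment], path: str | os.PathLike) -> None:
    """Write the per-member family table (TSV, one row per member gene)."""
    if not families:
        raise ValueError("no families to write")
    with open(path, "w") as fh:
        fh.write("family_id\tcategory\tgenome_count\tgenome_id\tgene_id\n")
        for fam in sorted(families, key=lambda f: f.family_id):
            for genome_id, gene_id in sorted(fam.members):
                fh.write(
                    f"{fam.family_id}\t{fam.category}\t{fam.genome_count}"
                    f"\t{genome_id}\t{gene_id}\n"
                )


def read_families(path: str | os.PathLike) -> list[FamilyAssignment]:
    """Read a family table written by :func:`write_families`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams = []
    for fid, grp in df.groupby("family_id", sort=True):
        members = frozenset(zip(grp["genome_id"], grp["gene_id"]))
        fams.append(
            FamilyAssignment(
                family_id=int(fid),
                members=members,
                category=grp["category"].iloc[0],
                genome_count=int(grp["genome_count"].iloc[0]),
            )
        )
    fams.sort(key=lambda f: f.family_id)
    return fams


def presence_absence_matrix(
    families: Sequence[FamilyAssignment], genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Family-by-genome matrix; cells count the member genes per genome."""
    data = {}
    for fam in families:
        counts = {g: 0 for g in genome_ids}
        for genome_id, _ in fam.members:
            counts[genome_id] += 1
        data[fam.family_id] = counts
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(genome_ids))
    df.index.name = "family_id"
    return df.sort_index()


def summarize_by_genome_count(
    families: Sequence[FamilyAssignment], n_genomes: int
) -> dict[int, int]:
    """Count families per number of genomes they appear in (1..n_genomes)."""
    summary = {g: 0 for g in range(1, n_genomes + 1)}
    for fam in families:
        if not 1 <= fam.genome_count <= n_genomes:
            raise ValueError(
                f"family {fam.family_id} spans {fam.genome_count} genomes, "
                f"outside [1, {n_genomes}]"
            )
        summary[fam.genome_count] += 1
    return summary


def write_summary(summary: dict[int, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("genome_count\tn_families\n")
        for g in sorted(summary):
            fh.write(f"{g}\t{summary[g]}\n")
        fh.write(f"total\t{sum(summary.values())}\n")


# --- GFF3 ingestion -----------------------------------------------------
#
# Annotated assemblies commonly arrive as GFF3 with the contig sequences
# embedded after a ##FASTA directive.  This thin converter extracts CDS
# features and translates them; the analysis itself always runs on amino
# acid sequences.

def gff3_to_geneset(
    path: str | os.PathLike,
    genome_id: str | None = None,
    translation_table: int = 11,
) -> GeneSet:
    """Extract CDS features from a GFF3 file with embedded FASTA and translate.

    ``translation_table`` follows NCBI numbering (11 = bacterial/archaeal).
    """
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    feature_lines: list[list[str]] = []
    fasta_chunk: list[str] = []
    in_fasta = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if in_fasta:
                fasta_chunk.append(line)
                continue
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 9 and fields[2] == "CDS":
                feature_lines.append(fields)
    if not fasta_chunk:
        raise ParseError(f"{path}: no embedded ##FASTA section")
    contigs: dict[str, str] = {}
    name = None
    buf: list[str] = []
    for line in fasta_chunk:
        if line.startswith(">"):
            if name is not None:
                contigs[name] = "".join(buf)
            name = line[1:].split()[0]
            buf = []
        else:
            buf.append(line.strip())
    if name is not None:
        contigs[name] = "".join(buf)

    genes: list[Gene] = []
    counter = 0
    for fields in feature_lines:
        seqid, _src, _type, start, end, _score, strand, phase, attrs = fields
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        counter += 1
        gene_id = attr_map.get("ID", f"cds{counter:05d}")
        nt = contigs[seqid][int(start) - 1 : int(end)]
        seq = Seq(nt)
        if strand == "-":
            seq = seq.reverse_complement()
        ph = int(phase) if phase in {"0", "1", "2"} else 0
        aa = str(seq[ph:].translate(table=translation_table)).rstrip("*")
        aa = sanitize_sequence(aa)
        if aa:
            genes.append(Gene(gene_id=gene_id, genome_id=genome_id, sequence=aa))
    if not genes:
        raise ParseError(f"{path}: no translatable CDS features")
    return GeneSet(genome_id=genome_id, genes=genes)
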