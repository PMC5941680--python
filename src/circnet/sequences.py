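"""Small nucleic-acid sequence helpers shared across the pipeline.

Genomic sequence is handled as DNA (ACGT); miRNAs and extracted circRNA
sequences are handled as RNA (ACGU). Conversion is a straight T<->U swap;
all comparisons are done uppercase.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMP)[::-1]


def is_rna(seq: str) -> bool:
    return set(seq.upper()) <= set("ACGUN")


def write_fasta(path, records, width: int = 70) -> None:
    """Write (name, sequence) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    """Read a (small) FASTA file into an ordered {name: sequence} dict."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
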