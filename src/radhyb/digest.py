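"""In silico multi-enzyme digestion and 3RAD locus prediction.

A reference is digested at the union of all enzyme cut points on the
forward strand (all three library enzymes have palindromic or
strand-symmetric recognition sequences, so a forward-strand scan is
complete).  Qualifying 3RAD loci are fragments flanked by one EcoRI and
one MseI cut in either orientation, inside the size-selection window and
not CviQI-flanked.  Sites touching undetermined (N) bases are not cut and
fragments spanning long N runs (assembly gaps) are discarded.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass

import pandas as pd

CHROM_END = "chromosome_end"


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str
    cut_offset: int  # bases after site start, top strand

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut offset outside recognition site")


ECORI = Enzyme("EcoRI", "GAATTC", 1)
MSEI = Enzyme("MseI", "TTAA", 1)
CVIQI = Enzyme("CviQI", "GTAC", 1)
DEFAULT_ENZYMES = (ECORI, MSEI, CVIQI)


@dataclass
class Fragment:
    """Digestion fragment; half-open [start, end) on one sequence."""

    seqid: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_sequence(
    seq: str, enzymes=DEFAULT_ENZYMES, seqid: str = "seq"
) -> list[Fragment]:
    """Cut one sequence at every enzyme recognition site.

    Overlapping site occurrences all cut; sites containing an N are not
    recognised and do not cut.  Fragments tile the sequence exactly.
    """
    if not seq:
        return []
    seq = seq.upper()
    cuts: dict[int, str] = {}
    for enz in enzymes:
        pattern = re.compile(f"(?={re.escape(enz.site)})")
        for m in pattern.finditer(seq):
            i, j = m.start(), m.start() + len(enz.site)
            # sites touching undetermined bases are not recognised
            if (i > 0 and seq[i - 1] == "N") or (j < len(seq) and seq[j] == "N"):
                continue
            cuts.setdefault(i + enz.cut_offset, enz.name)
    points = sorted(cuts)
    frags = []
    prev, prev_enz = 0, CHROM_END
    for p in points:
        frags.append(Fragment(seqid, prev, p, prev_enz, cuts[p]))
        prev, prev_enz = p, cuts[p]
    frags.append(Fragment(seqid, prev, len(seq), prev_enz, CHROM_END))
    return frags


def _read_fasta(path):
    opener = gzip.open if str(path).endswith(".gz") else open
    name, chunks = None, []
    try:
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        yield name, "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                elif line:
                    if name is None:
                        raise ValueError("malformed FASTA: sequence before header")
                    chunks.append(line)
        if name is not None:
            yield name, "".join(chunks)
        elif not chunks:
            return
    except UnicodeDecodeError as exc:
        raise ValueError(f"unreadable FASTA {path}") from exc


def predict_loci(
    genome,
    size_window: tuple[int, int] = (350, 450),
    require_pair: frozenset | set = frozenset({"EcoRI", "MseI"}),
    exclude_if_cviqi_end: bool = True,
    adapter_offset: int = 0,
    max_n_run: int = 10,
    enzymes=DEFAULT_ENZYMES,
) -> pd.DataFrame:
    """Predict size-selected 3RAD loci from a genome.

    ``genome`` is a FASTA path or a mapping of name -> sequence.  The
    window is inclusive and compares insert length; ``adapter_offset``
    shifts it to emulate selection on adapter-ligated molecules.  Returns
    one row per internal fragment with qualifying flags; qualifying loci
    satisfy all flags.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        records = _read_fasta(genome)
    else:
        records = genome.items()
    lo = size_window[0] - adapter_offset
    hi = size_window[1] - adapter_offset
    rows = []
    gap = re.compile("N" * max_n_run) if max_n_run else None
    for name, seq in records:
        seq = seq.upper()
        for frag in digest_sequence(seq, enzymes, seqid=name):
            ends = {frag.left_enzyme, frag.right_enzyme}
            pair_ok = ends == set(require_pair)
            size_ok = lo <= frag.length <= hi
            cviqi_ok = not (
                exclude_if_cviqi_end and CVIQI.name in (frag.left_enzyme, frag.right_enzyme)
            )
            internal = CHROM_END not in ends
            gap_ok = not (gap and gap.search(seq[frag.start: frag.end]))
            rows.append(
                {
                    "seqid": frag.seqid,
                    "start": frag.start,
                    "end": frag.end,
                    "length": frag.length,
                    "left_enzyme": frag.left_enzyme,
                    "right_enzyme": frag.right_enzyme,
                    "internal": internal,
                    "pair_ok": pair_ok,
                    "size_ok": size_ok,
                    "no_cviqi_end": cviqi_ok,
                    "no_gap": gap_ok,
                    "qualifies": internal and pair_ok and size_ok and cviqi_ok and gap_ok,
                }
            )
    return pd.DataFrame(rows)


def count_loci(prediction: pd.DataFrame) -> int:
    return int(prediction["qualifies"].sum()) if len(prediction) else 0


def to_bed(prediction: pd.DataFrame, path, qualifying_only: bool = True) -> None:
    df = prediction[prediction["qualifies"]] if qualifying_only else prediction
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples()):
            fh.write(
                f"{row.seqid}\t{row.start}\t{row.end}\tlocus{i:06d}\t"
                f"{row.length}\t+\n"
            )
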