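"""Reading the subset of the PDB format this tool needs.

The pipeline consumes: SEQRES sequences per chain, DBREF chain order,
SHEET records grouped by sheet id in registration order, HELIX extents,
and CA coordinates keyed by (chain, author residue number).  Parsing is
delegated to gemmi; DBREF chain order is scanned from the raw text since
gemmi does not surface DBREF records.

Entry-level policy mirrors the original screening: nucleic-acid chains are
not protein chains, chains under 50 residues are flagged as peptides, and
only the first protein chain in DBREF order is analyzed.  SEQRES indices
are 1-based inclusive everywhere; author numbering appears only at this
I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gemmi
import numpy as np

__all__ = [
    "MIN_CHAIN_LENGTH",
    "ChainRecord",
    "StrandRecord",
    "SheetRecord",
    "Structure",
    "NotParseableError",
    "NoAnalyzableChainError",
    "NumberingGapError",
    "parse_structure",
    "select_analysis_chain",
    "map_author_to_index",
    "strand_indices",
]

#: Chains shorter than this are peptides, excluded from analysis.
MIN_CHAIN_LENGTH = 50

ResidueKey = tuple[int, str]  # (author number, insertion code)


class NotParseableError(ValueError):
    """Input text is not a usable PDB entry (e.g. no SEQRES)."""


class NoAnalyzableChainError(ValueError):
    """No protein chain of sufficient length referenced by DBREF."""


class NumberingGapError(KeyError):
    """An author residue number cannot be mapped to a SEQRES index."""


@dataclass
class ChainRecord:
    chain_id: str
    sequence: list[str]
    author_numbers: list[ResidueKey]
    ca_count: int
    is_protein: bool
    #: author number of the residue at SEQRES index 1 (from DBREF when present)
    first_author_number: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def below_length_threshold(self) -> bool:
        return len(self.sequence) < MIN_CHAIN_LENGTH

    @property
    def has_missing_residues(self) -> bool:
        """CA count below SEQRES length signals unmodelled residues."""
        return self.ca_count < len(self.sequence)


@dataclass(frozen=True)
class StrandRecord:
    sheet_id: str
    strand_ordinal: int
    chain_id: str
    begin_residue: ResidueKey
    end_residue: ResidueKey
    sense: int = 0


@dataclass
class SheetRecord:
    sheet_id: str
    strands: list[StrandRecord]
    declared_strand_count: int = 0

    def __post_init__(self) -> None:
        if not self.strands:
            raise ValueError(f"sheet {self.sheet_id!r} has no strands")


@dataclass
class Structure:
    chains: list[ChainRecord]
    sheets: list[SheetRecord]
    helices: list[tuple[str, ResidueKey, ResidueKey]]
    ca_coordinates: dict[tuple[str, ResidueKey], np.ndarray]
    dbref_chain_order: list[str] = field(default_factory=list)


def _addr_key(addr: gemmi.AtomAddress) -> ResidueKey:
    icode = addr.res_id.seqid.icode
    return (addr.res_id.seqid.num, icode if icode.strip() else " ")


def _scan_dbref_order(pdb_text: str) -> list[str]:
    order: list[str] = []
    for line in pdb_text.splitlines():
        if line.startswith(("DBREF ", "DBREF1")):
            if len(line) > 12:
                cid = line[12].strip() or " "
                if cid not in order:
                    order.append(cid)
    return order


def _scan_dbref_begin(pdb_text: str) -> dict[str, int]:
    begins: dict[str, int] = {}
    for line in pdb_text.splitlines():
        if line.startswith(("DBREF ", "DBREF1")):
            try:
                cid = line[12].strip() or " "
                begin = int(line[14:18])
            except (ValueError, IndexError):
                continue
            begins.setdefault(cid, begin)
    return begins


def parse_structure(pdb_text: str) -> Structure:
    """Parse a PDB-format entry into the records the pipeline consumes.

    Raises :class:`NotParseableError` when no SEQRES sequence is present.
    Malformed SHEET strands are dropped with a warning rather than failing
    the whole entry.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as err:
        raise NotParseableError(f"cannot parse PDB text: {err}") from None
    st.setup_entities()

    seqres: dict[str, list[str]] = {}
    polytype: dict[str, gemmi.PolymerType] = {}
    for ent in st.entities:
        if ent.full_sequence:
            seqres[ent.name] = [m.split(",")[0] for m in ent.full_sequence]
            polytype[ent.name] = ent.polymer_type
    if not seqres:
        raise NotParseableError("no SEQRES records found")

    dbref_order = _scan_dbref_order(pdb_text)
    dbref_begin = _scan_dbref_begin(pdb_text)

    ca: dict[tuple[str, ResidueKey], np.ndarray] = {}
    observed: dict[str, list[ResidueKey]] = {}
    ca_count: dict[str, int] = {}
    if len(st):  # first MODEL only
        model = st[0]
        for chain in model:
            for res in chain:
                icode = res.seqid.icode if res.seqid.icode.strip() else " "
                key = (res.seqid.num, icode)
                observed.setdefault(chain.name, []).append(key)
                for atom in res:
                    if atom.name == "CA" and atom.element.name == "C":
                        ca_count[chain.name] = ca_count.get(chain.name, 0) + 1
                        ca.setdefault(
                            (chain.name, key),
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                        break

    chains: list[ChainRecord] = []
    for cid, seq in seqres.items():
        ptype = polytype.get(cid, gemmi.PolymerType.Unknown)
        is_protein = ptype in (
            gemmi.PolymerType.PeptideL,
            gemmi.PolymerType.PeptideD,
            gemmi.PolymerType.Unknown,
        ) and not _looks_nucleic(seq)
        chains.append(
            ChainRecord(
                chain_id=cid,
                sequence=seq,
                author_numbers=observed.get(cid, []),
                ca_count=ca_count.get(cid, 0),
                is_protein=is_protein,
                first_author_number=dbref_begin.get(cid),
            )
        )

    sheets: list[SheetRecord] = []
    for sh in st.sheets:
        strands: list[StrandRecord] = []
        for ordinal, s in enumerate(sh.strands, start=1):
            try:
                strands.append(
                    StrandRecord(
                        sheet_id=sh.name,
                        strand_ordinal=ordinal,
                        chain_id=s.start.chain_name,
                        begin_residue=_addr_key(s.start),
                        end_residue=_addr_key(s.end),
                        sense=int(s.sense),
                    )
                )
            except (AttributeError, ValueError) as err:  # malformed record
                warnings.warn(f"dropping malformed strand in sheet {sh.name}: {err}")
        if strands:
            sheets.append(SheetRecord(sh.name, strands, declared_strand_count=len(sh.strands)))

    helices = [
        (h.start.chain_name, _addr_key(h.start), _addr_key(h.end)) for h in st.helices
    ]

    return Structure(chains, sheets, helices, ca, dbref_chain_order=dbref_order)


_NUCLEIC_CODES = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"}


def _looks_nucleic(sequence: Iterable[str]) -> bool:
    seq = list(sequence)
    if not seq:
        return False
    hits = sum(1 for c in seq if c.upper() in _NUCLEIC_CODES)
    return hits > len(seq) / 2


def select_analysis_chain(structure: Structure) -> ChainRecord:
    """The first protein chain (>= 50 residues) in DBREF order.

    Falls back to SEQRES record order when no DBREF records exist.
    """
    by_id = {c.chain_id: c for c in structure.chains}
    order = [cid for cid in structure.dbref_chain_order if cid in by_id]
    order += [c.chain_id for c in structure.chains if c.chain_id not in order]
    for cid in order:
        chain = by_id[cid]
        if chain.is_protein and not chain.below_length_threshold:
            return chain
    raise NoAnalyzableChainError(
        "no protein chain of >= 50 residues referenced by DBREF"
    )


def map_author_to_index(chain: ChainRecord, author: int | ResidueKey) -> int:
    """Map an author residue number to a 1-based SEQRES index.

    Without insertion codes the mapping is arithmetic from the DBREF begin
    number (or the first observed residue).  With insertion codes present
    the mapping is by ordered occurrence among observed residues.
    """
    key: ResidueKey = (author, " ") if isinstance(author, int) else (author[0], author[1] or " ")
    has_icodes = any(ic != " " for _, ic in chain.author_numbers)
    if has_icodes:
        # ordered occurrence: observed residue k is SEQRES position k + lead,
        # where lead aligns the first observed residue via the DBREF begin.
        try:
            pos = chain.author_numbers.index(key)
        except ValueError:
            raise NumberingGapError(
                f"residue {key} not observed in chain {chain.chain_id}"
            ) from None
        lead = 0
        if chain.first_author_number is not None and chain.author_numbers:
            lead = chain.author_numbers[0][0] - chain.first_author_number
        idx = pos + 1 + lead
    else:
        if chain.first_author_number is not None:
            base = chain.first_author_number
        elif chain.author_numbers:
            base = chain.author_numbers[0][0]
        else:
            base = 1
        idx = key[0] - base + 1
    if not 1 <= idx <= len(chain.sequence):
        raise NumberingGapError(
            f"author residue {key} maps outside SEQRES 1..{len(chain.sequence)} "
            f"of chain {chain.chain_id}"
        )
    return idx


def strand_indices(chain: ChainRecord, strand: StrandRecord) -> tuple[int, int]:
    """SEQRES index range (begin, end) of a strand, both inclusive."""
    b = map_author_to_index(chain, strand.begin_residue)
    e = map_author_to_index(chain, strand.end_residue)
    if b > e:
        raise NumberingGapError(
            f"strand {strand.sheet_id}:{strand.strand_ordinal} extent reversed "
            f"({strand.begin_residue} > {strand.end_residue})"
        )
    return b, e
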