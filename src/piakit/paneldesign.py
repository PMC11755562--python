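"""Blocking-peptide panel generation.

Four positioned families tile the protein chain -- original
secondary-structure windows, staggered junction peptides centred on the gap
between consecutive windows, 6-mer N/middle/C fragments of selected parents,
and a deletion split of one parent -- plus composition-preserving randomized
controls with no chain position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from . import fixtures
from .seqcore import Interval, ProteinChain, validate_sequence

logger = logging.getLogger(__name__)

CATEGORIES = frozenset({
    "original", "staggered", "short_N", "short_M", "short_C",
    "deletion_N", "deletion_C", "randomized",
})


class PanelAssemblyError(ValueError):
    """Generated panel disagrees with the packaged golden sequences."""


@dataclass(frozen=True)
class PeptideRecord:
    """A named peptide: category, chain interval (None for randomized),
    sequence, and the parent peptide it derives from, if any."""

    id: str
    category: str
    sequence: str
    interval: Optional[Interval] = None
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        object.__setattr__(self, "sequence", validate_sequence(
            self.sequence, name=self.id))
        if self.interval is not None and len(self.interval) != len(self.sequence):
            raise ValueError(
                f"{self.id}: interval {self.interval} does not fit "
                f"{len(self.sequence)}-mer")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Panel:
    """An ordered, id-unique collection of peptides."""

    peptides: list[PeptideRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate peptide ids: {sorted(dupes)}")

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.peptides)

    def __len__(self) -> int:
        return len(self.peptides)

    def __getitem__(self, peptide_id: str) -> PeptideRecord:
        for p in self.peptides:
            if p.id == peptide_id:
                return p
        raise KeyError(peptide_id)

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def extend(self, other: "Panel") -> "Panel":
        return Panel(self.peptides + other.peptides,
                     {**self.provenance, **other.provenance})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.peptides:
            rows.append({
                "id": p.id, "category": p.category,
                "start": p.interval.start if p.interval else None,
                "end": p.interval.end if p.interval else None,
                "sequence": p.sequence, "parent_id": p.parent_id,
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Panel":
        frame = pd.read_csv(path, sep="\t", comment="#")
        peptides = []
        for r in frame.itertuples():
            interval = None
            if pd.notna(r.start) and pd.notna(r.end):
                interval = Interval(int(r.start), int(r.end))
            parent = r.parent_id if pd.notna(r.parent_id) else None
            peptides.append(PeptideRecord(r.id, r.category, r.sequence,
                                          interval, parent))
        return cls(peptides, {"source": str(path)})


def design_original(chain: ProteinChain,
                    windows: Iterable[tuple[str, Interval]],
                    min_length: int = 6) -> Panel:
    """One peptide per window, reading the chain substring at the window."""
    peptides = []
    for pid, window in windows:
        if len(window) < min_length:
            raise ValueError(
                f"{pid}: window {window} shorter than minimum {min_length}")
        peptides.append(PeptideRecord(pid, "original",
                                      chain.subsequence(window), window))
    return Panel(peptides, {"design": "original", "chain": chain.name})


def _staggered_span(end_left: int, start_right: int, length: int) -> tuple[int, int]:
    """Start/end of the length-L window symmetric about the junction midpoint.

    The centre is c = (end_left + start_right) / 2; the window starts at
    c - (L-1)/2, rounded half-up so that an even-length window about an
    integer centre takes the C-terminal-shifted choice.
    """
    center = (end_left + start_right) / 2.0
    start = int(Decimal(str(center - (length - 1) / 2.0))
                .quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return start, start + length - 1


def design_staggered(chain: ProteinChain,
                     original_windows: list[tuple[str, Interval]],
                     length_map: dict[str, int],
                     clip: bool = False) -> Panel:
    """Junction peptides between consecutive original windows.

    For each consecutive window pair the peptide is centred on the midpoint
    of (end of the left window, start of the right window); its id is the
    left window's id with ".5" appended, and its length comes from
    ``length_map`` -- junction ids absent from the map are skipped (the
    published panel stops at BP22.5). Windows are taken as given, typos
    included: the staggered design demonstrably used the printed
    coordinates.
    """
    if len(original_windows) < 2:
        raise ValueError("need at least two original windows")
    peptides = []
    for (left_id, left), (_right_id, right) in zip(original_windows,
                                                   original_windows[1:]):
        pid = f"{left_id}.5"
        length = length_map.get(pid)
        if length is None:
            continue
        if not 6 <= length <= 20:
            raise ValueError(f"{pid}: length {length} outside [6, 20]")
        start, end = _staggered_span(left.end, right.start, length)
        if start < 1 or end > len(chain):
            if not clip:
                raise ValueError(
                    f"{pid}: window {start}-{end} exceeds chain bounds")
            clipped = Interval(max(start, 1), min(end, len(chain)))
            logger.warning("%s: clipped %d-%d to %s", pid, start, end, clipped)
            interval = clipped
        else:
            interval = Interval(start, end)
        peptides.append(PeptideRecord(pid, "staggered",
                                      chain.subsequence(interval), interval))
    return Panel(peptides, {"design": "staggered", "lengths": dict(length_map)})


def design_short(chain: ProteinChain, parents: Iterable[PeptideRecord],
                 k: int = 6,
                 overrides: dict[str, str] | None = None) -> Panel:
    """k-mer N-terminal, middle and C-terminal fragments of each parent.

    The middle window starts at offset floor((L-k)/2). ``overrides`` maps a
    fragment id to a replacement sequence (located on the chain); each use
    is logged as a deviation from the rule.
    """
    overrides = overrides or {}
    peptides = []
    for parent in parents:
        L = len(parent)
        if L < k:
            raise ValueError(f"{parent.id}: parent shorter than k={k}")
        offset_m = (L - k) // 2
        for suffix, offset in (("N", 0), ("M", offset_m), ("C", L - k)):
            pid = f"{parent.id}{suffix}"
            if pid in overrides:
                seq = validate_sequence(overrides[pid], name=pid)
                interval = chain.locate(seq)
                logger.warning(
                    "%s: override %r replaces rule fragment %r", pid, seq,
                    parent.sequence[offset:offset + k])
            else:
                seq = parent.sequence[offset:offset + k]
                interval = None
                if parent.interval is not None:
                    interval = Interval(parent.interval.start + offset,
                                        parent.interval.start + offset + k - 1)
            peptides.append(PeptideRecord(pid, f"short_{suffix}", seq,
                                          interval, parent.id))
    return Panel(peptides, {"design": "short", "k": k,
                            "overrides": sorted(overrides)})


def design_deletions(parent: PeptideRecord, sub_len: int,
                     overlap: int) -> Panel:
    """Split a parent into an N-side and a C-side ``sub_len``-mer that
    overlap by ``overlap`` residues."""
    L = len(parent)
    if not 0 < sub_len <= L:
        raise ValueError(f"sub_len {sub_len} invalid for {L}-mer parent")
    if not 0 <= overlap < sub_len:
        raise ValueError(f"overlap {overlap} invalid for sub_len {sub_len}")
    c_start = sub_len - overlap  # 0-based
    if c_start + sub_len > L:
        raise ValueError(
            f"{parent.id}: no room for C-side window "
            f"(sub_len {sub_len}, overlap {overlap}, parent {L}-mer)")
    pieces = []
    for suffix, start in (("N", 0), ("C", c_start)):
        seq = parent.sequence[start:start + sub_len]
        interval = None
        if parent.interval is not None:
            interval = Interval(parent.interval.start + start,
                                parent.interval.start + start + sub_len - 1)
        pieces.append(PeptideRecord(f"{parent.id}{suffix}",
                                    f"deletion_{suffix}", seq,
                                    interval, parent.id))
    return Panel(pieces, {"design": "deletion", "sub_len": sub_len,
                          "overlap": overlap})


def randomize(parent: PeptideRecord, n_variants: int, seed: int) -> Panel:
    """Seeded uniform shuffles of the parent sequence (Fisher-Yates).

    Each variant is a permutation, so every composition-only descriptor is
    preserved by construction. Derangement is not enforced.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    peptides = []
    for i in range(1, n_variants + 1):
        letters = np.array(list(parent.sequence))
        rng.shuffle(letters)
        peptides.append(PeptideRecord(f"{parent.id}R{i}", "randomized",
                                      "".join(letters), None, parent.id))
    return Panel(peptides, {"design": "randomized", "seed": seed,
                            "parent": parent.id})


def build_paper_panel(chain: ProteinChain | None = None) -> Panel:
    """The published 85-peptide panel, regenerated from the design rules.

    25 original + 22 staggered + 2 deletion + 30 short peptides are derived
    from the chain by the family rules (with the packaged override list for
    the four rule-deviating short fragments); the 6 randomized sequences are
    taken from the packaged table, since a manual card-drawing shuffle has
    no reproducible seed. Every generated sequence is checked against the
    printed table; any difference raises :class:`PanelAssemblyError`.
    """
    if chain is None:
        chain = fixtures.ecori_chain()
    windows = fixtures.printed_windows("original")
    # The one original window whose printed width disagrees with its
    # sequence (BP22) is corrected by locating the sequence on the chain;
    # the staggered design below intentionally keeps the printed windows.
    printed = fixtures.printed_sequences()
    corrected = []
    for pid, window in windows:
        seq = printed[pid]
        if len(window) != len(seq):
            relocated = chain.locate(seq)
            logger.warning("%s: printed interval %s relocated to %s",
                           pid, window, relocated)
            corrected.append((pid, relocated))
        else:
            corrected.append((pid, window))

    panel = design_original(chain, corrected)
    panel = panel.extend(design_staggered(chain, windows,
                                          fixtures.staggered_length_map()))
    panel = panel.extend(design_deletions(panel["BP19.5"], sub_len=6,
                                          overlap=2))
    overrides = {pid: printed[pid] for pid in fixtures.SHORT_OVERRIDES}
    parents = [panel[pid] for pid in fixtures.SHORT_PARENTS]
    panel = panel.extend(design_short(chain, parents, k=6,
                                      overrides=overrides))
    randomized = [PeptideRecord(r.id, "randomized", r.sequence, None,
                                r.parent_id)
                  for r in fixtures.panel_table().itertuples()
                  if r.category == "randomized"]
    panel = panel.extend(Panel(randomized, {"randomized": "as printed"}))

    diffs = [f"{p.id}: generated {p.sequence} != printed {printed[p.id]}"
             for p in panel if p.sequence != printed[p.id]]
    missing = set(printed) - set(panel.ids())
    if missing:
        diffs.append(f"missing ids: {sorted(missing)}")
    if diffs:
        raise PanelAssemblyError("; ".join(diffs))
    panel.provenance["design"] = "paper"
    return panel
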