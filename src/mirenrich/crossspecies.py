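"""Mouse-human miRNA harmonization by seed sequence and name.

Mature miRNAs from the two species are paired when they share an
identical seed (nucleotides 2-7 of the mature sequence, the primary
determinant of target recognition) and a sufficiently similar miRBase
name. Only one-to-one (seed, base-name) pairs are flagged unique;
many-to-many groups are reported separately so paralog families are
never silently collapsed.
"""
from __future__ import annotations

import re
from typing import NamedTuple, Sequence

import edlib
import numpy as np
import pandas as pd

from .io_formats import MatureMirnaRecord


def extract_seed(record) -> str:
    """Seed = characters at 1-based positions 2..7 of the mature sequence."""
    seq = record.sequence if isinstance(record, MatureMirnaRecord) else str(record)
    seq = seq.upper().replace("T", "U")
    if len(seq) < 7:
        name = getattr(record, "name", seq)
        raise ValueError(f"sequence of {name!r} shorter than 7 nt; no seed")
    return seq[1:7]


class NormalizedName(NamedTuple):
    base_name: str
    arm: str | None
    species: str | None
    parsed: bool


_SPECIES_RE = re.compile(r"^([a-z]{3})-")
_ARM_RE = re.compile(r"-(5p|3p)$")
_NAME_RE = re.compile(r"^(mir|let|lin)-\S+$")


def normalize_mirna_name(name: str) -> NormalizedName:
    """Decompose a miRBase mature name into (base_name, arm, species).

    Case-folds, strips the 3-letter species prefix and the -5p/-3p arm
    suffix; lettered/numbered paralog suffixes stay in the base name
    (``hsa-miR-18a-5p`` -> ``mir-18a``, ``mmu-let-7c-1-3p`` ->
    ``let-7c-1``). Unparseable names pass through flagged, never error.
    """
    if not name or not name.strip():
        return NormalizedName("", None, None, False)
    s = name.strip().lower()
    sp = _SPECIES_RE.match(s)
    species = None
    # "mir-", "let-", "lin-" are family stems, never species codes
    if sp and sp.group(1) not in ("mir", "let", "lin"):
        species = sp.group(1)
        s = s[len(species) + 1:]
    arm = None
    am = _ARM_RE.search(s)
    if am:
        arm = am.group(1)
        s = s[: am.start()]
    parsed = bool(_NAME_RE.match(s))
    return NormalizedName(s, arm, species, parsed)


def name_similarity(a: NormalizedName, b: NormalizedName) -> float:
    """Tiered name similarity in [0, 1].

    1.0 when base name and arm both agree; 0.8 when base names agree but
    the arms differ or one is missing; otherwise 1 - edit distance over
    the longer base name.
    """
    if a.base_name == b.base_name:
        return 1.0 if (a.arm == b.arm and a.arm is not None) else \
            (1.0 if a.arm is None and b.arm is None else 0.8)
    longest = max(len(a.base_name), len(b.base_name))
    if longest == 0:
        return 0.0
    dist = edlib.align(a.base_name, b.base_name)["editDistance"]
    return max(0.0, 1.0 - dist / longest)


def match_mouse_human(mouse: Sequence[MatureMirnaRecord],
                      human: Sequence[MatureMirnaRecord],
                      min_name_score: float = 0.8):
    """Pair mouse and human matures on identical seed plus name similarity.

    Candidate pairs share the exact 6-mer seed and have name similarity
    >= ``min_name_score``. The uniqueness filter keeps pairs whose
    (seed, base-name) combination is one-to-one in both directions;
    ambiguous groups (paralogs sharing a seed and name) are returned in
    a separate report. Returns ``(table, ambiguities)`` where the table
    has one row per candidate pair with a ``unique`` flag.
    """
    if not mouse or not human:
        raise ValueError("both record lists must be nonempty")
    rows = []
    h_by_seed: dict[str, list] = {}
    for h in human:
        h_by_seed.setdefault(extract_seed(h), []).append(h)
    for mrec in mouse:
        seed = extract_seed(mrec)
        mn = normalize_mirna_name(mrec.name)
        for hrec in h_by_seed.get(seed, ()):
            hn = normalize_mirna_name(hrec.name)
            score = name_similarity(mn, hn)
            if score >= min_name_score:
                rows.append({"mouse_name": mrec.name, "human_name": hrec.name,
                             "seed": seed, "name_score": score,
                             "mouse_base": mn.base_name, "mouse_arm": mn.arm,
                             "human_base": hn.base_name, "human_arm": hn.arm})
    table = pd.DataFrame(rows, columns=["mouse_name", "human_name", "seed",
                                        "name_score", "mouse_base", "mouse_arm",
                                        "human_base", "human_arm"])
    if table.empty:
        table["unique"] = pd.Series(dtype=bool)
        return table, []
    # one-to-one in both directions: each mature may participate in only
    # one candidate pair (all of a mature's pairs share its seed)
    n_per_mouse = table.groupby("mouse_name")["human_name"].transform("size")
    n_per_human = table.groupby("human_name")["mouse_name"].transform("size")
    table["unique"] = (n_per_mouse == 1) & (n_per_human == 1)
    ambiguities = []
    for seed, sub in table[~table["unique"]].groupby("seed"):
        ambiguities.append({"seed": seed,
                            "base_names": sorted(set(sub["mouse_base"])
                                                 | set(sub["human_base"])),
                            "mouse_names": sorted(set(sub["mouse_name"])),
                            "human_names": sorted(set(sub["human_name"]))})
    return table.reset_index(drop=True), ambiguities


def unique_match_counts(table: pd.DataFrame) -> dict:
    """Tally unique pairs both as mature names and as collapsed base names."""
    uniq = table[table["unique"]]
    return {"mature_pairs": int(len(uniq)),
            "base_name_pairs": int(uniq["mouse_base"].nunique())}
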