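"""Word lists for targets and attributes.

A :class:`Lexicon` is a named, ordered list of lexemes (possibly multiword)
playing either the *target* role (the category being measured: AI terms,
demographic group terms, occupations) or the *attribute* role (the poles of a
stereotype dimension: high/low competence, high/low warmth). A
:class:`ContrastPair` binds the two poles of one dimension together.

Lexemes are normalized on construction: case-folded, with internal whitespace
collapsed to single spaces. Normalization is idempotent; duplicates that
collapse under it are an error (silent deduplication would change effect
sizes invisibly).
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .errors import ContentError, SchemaError

Role = Literal["target", "attribute"]

_POLARITIES = {"high", "low", "advantaged", "disadvantaged", "none"}
_DIMENSIONS = {"competence", "warmth", "gender", "age", "class", "race", "occupation"}


def normalize_lexeme(lexeme: str) -> str:
    """Case-fold and collapse internal whitespace. Idempotent."""
    return " ".join(lexeme.casefold().split())


@dataclass(frozen=True)
class Lexicon:
    """A named, polarity-labeled word list.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"ai_terms"`` or ``"kurdi_competence_high"``.
    role : {"target", "attribute"}
    words : sequence of str
        Ordered lexemes; normalized on construction, order preserved.
    polarity : optional {"high", "low", "advantaged", "disadvantaged", "none"}
    dimension : optional {"competence", "warmth", "gender", "age", "class",
        "race", "occupation"}
    source : str
        Free-text provenance of the list.
    """

    name: str
    role: Role
    words: tuple[str, ...]
    polarity: Optional[str] = None
    dimension: Optional[str] = None
    source: str = ""

    def __post_init__(self):
        if self.role not in ("target", "attribute"):
            raise SchemaError(f"role must be 'target' or 'attribute', got {self.role!r}")
        if self.polarity is not None and self.polarity not in _POLARITIES:
            raise SchemaError(f"unknown polarity {self.polarity!r}")
        if self.dimension is not None and self.dimension not in _DIMENSIONS:
            raise SchemaError(f"unknown dimension {self.dimension!r}")
        norm = tuple(normalize_lexeme(w) for w in self.words)
        if not norm:
            raise ContentError(f"lexicon '{self.name}' has an empty word list")
        seen: dict[str, int] = {}
        dups = []
        for w in norm:
            if w in seen:
                dups.append(w)
            seen[w] = 1
        if dups:
            raise ContentError(
                f"lexicon '{self.name}' has duplicate lexemes after normalization: "
                + ", ".join(sorted(set(dups)))
            )
        object.__setattr__(self, "words", norm)

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


@dataclass(frozen=True)
class ContrastPair:
    """Two same-dimension lexicons forming the poles of a contrast.

    ``high`` carries the high/advantaged pole, ``low`` the low/disadvantaged
    one. The two word sets must be disjoint and share role and dimension.
    """

    high: Lexicon
    low: Lexicon
    label: str

    def __post_init__(self):
        if self.high.role != self.low.role:
            raise ContentError(
                f"contrast '{self.label}': poles have different roles "
                f"({self.high.role} vs {self.low.role})"
            )
        if self.high.dimension != self.low.dimension:
            raise ContentError(
                f"contrast '{self.label}': poles have different dimensions "
                f"({self.high.dimension} vs {self.low.dimension})"
            )
        overlap = set(self.high.words) & set(self.low.words)
        if overlap:
            raise ContentError(
                f"contrast '{self.label}': poles share lexemes: "
                + ", ".join(sorted(overlap))
            )

    def mirror(self) -> "ContrastPair":
        """The pair with high and low exchanged (an involution)."""
        return ContrastPair(high=self.low, low=self.high, label=self.label)


def make_contrast(high: Lexicon, low: Lexicon, label: str) -> ContrastPair:
    """Validate and build a :class:`ContrastPair`."""
    return ContrastPair(high=high, low=low, label=label)


_CSV_COLUMNS = ["word", "role", "polarity", "dimension", "source"]


def load_lexicon(path: str | Path, format: Optional[str] = None,
                 name: Optional[str] = None) -> Lexicon:
    """Read a lexicon from CSV or JSON.

    CSV files carry one word per row with columns
    ``word,role,polarity,dimension,source``; role/polarity/dimension/source
    must be constant over rows (one lexicon per file). JSON files carry one
    object with keys ``name, role, polarity, dimension, source, words``.
    File order is preserved. ``format`` is inferred from the suffix when not
    given; ``name`` defaults to the file stem for CSV.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        data = json.loads(path.read_text())
        missing = {"name", "role", "words"} - set(data)
        if missing:
            raise SchemaError(f"{path}: JSON lexicon missing keys: {sorted(missing)}")
        return Lexicon(
            name=data["name"], role=data["role"], words=tuple(data["words"]),
            polarity=data.get("polarity") or None,
            dimension=data.get("dimension") or None,
            source=data.get("source", ""),
        )
    if fmt != "csv":
        raise SchemaError(f"unknown lexicon format {fmt!r}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "word" not in reader.fieldnames:
            raise SchemaError(f"{path}: CSV lexicon needs a 'word' column")
        rows = list(reader)
    if not rows:
        raise ContentError(f"{path}: empty lexicon file")
    meta = {k: (rows[0].get(k) or "") for k in _CSV_COLUMNS[1:]}
    for r in rows:
        for k in _CSV_COLUMNS[1:]:
            if (r.get(k) or "") != meta[k]:
                raise ContentError(f"{path}: column '{k}' is not constant over rows")
    if not meta["role"]:
        raise SchemaError(f"{path}: CSV lexicon needs a 'role' value")
    return Lexicon(
        name=name or path.stem, role=meta["role"],
        words=tuple(r["word"] for r in rows),
        polarity=meta["polarity"] or None, dimension=meta["dimension"] or None,
        source=meta["source"],
    )


def write_lexicon(lexicon: Lexicon, path: str | Path,
                  format: Optional[str] = None) -> None:
    """Write a lexicon to CSV or JSON (the inverse of :func:`load_lexicon`)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {
            "name": lexicon.name, "role": lexicon.role,
            "polarity": lexicon.polarity, "dimension": lexicon.dimension,
            "source": lexicon.source, "words": list(lexicon.words),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for w in lexicon.words:
            writer.writerow([w, lexicon.role, lexicon.polarity or "",
                             lexicon.dimension or "", lexicon.source])


def example_lexicons() -> dict[str, Lexicon]:
    """A small illustrative lexicon set mirroring the published dictionaries'
    structure (AI targets, competence/warmth attribute poles, demographic group
    poles). Real analyses supply the full dictionaries as files; these are for
    demonstrations and smoke tests.
    """
    mk = lambda name, role, words, pol=None, dim=None, src="illustrative": Lexicon(
        name, role, tuple(words), pol, dim, src)
    return {
        "ai": mk("ai", "target",
                 ["artificial intelligence", "ai", "robot", "machine learning",
                  "neural network", "chatbot", "algorithm", "automation"],
                 "none"),
        "competence_high": mk("competence_high", "attribute",
                              ["competent", "intelligent", "skilled", "capable",
                               "efficient", "clever"], "high", "competence"),
        "competence_low": mk("competence_low", "attribute",
                             ["incompetent", "stupid", "unskilled", "incapable",
                              "inefficient", "foolish"], "low", "competence"),
        "warmth_high": mk("warmth_high", "attribute",
                          ["warm", "friendly", "kind", "trustworthy",
                           "sincere", "caring"], "high", "warmth"),
        "warmth_low": mk("warmth_low", "attribute",
                         ["cold", "hostile", "cruel", "untrustworthy",
                          "insincere", "indifferent"], "low", "warmth"),
        "gender_adv": mk("gender_adv", "target",
                         ["man", "men", "he", "him", "male"],
                         "advantaged", "gender"),
        "gender_dis": mk("gender_dis", "target",
                         ["woman", "women", "she", "her", "female"],
                         "disadvantaged", "gender"),
        "age_adv": mk("age_adv", "target",
                      ["young", "youth", "teenager"], "advantaged", "age"),
        "age_dis": mk("age_dis", "target",
                      ["old", "elderly", "senior"], "disadvantaged", "age"),
        "class_adv": mk("class_adv", "target",
                        ["rich", "wealthy", "affluent"], "advantaged", "class"),
        "class_dis": mk("class_dis", "target",
                        ["poor", "impoverished", "needy"], "disadvantaged", "class"),
        "race_adv": mk("race_adv", "target",
                       ["white", "caucasian", "european"], "advantaged", "race"),
        "race_dis": mk("race_dis", "target",
                       ["black", "asian", "hispanic"], "disadvantaged", "race"),
    }
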