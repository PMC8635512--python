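"""Curated reference catalogue of putative RNA-binding proteins (RBPs).

The catalogue merges experimentally identified RBPs (RNA-interactome
capture) with computationally predicted ones (presence of known
RNA-binding domains), removes curation-flagged entries (histones,
known contaminants, mitochondrial RBPs) and carries two annotation
layers: RNA-binding domains (RBDs, e.g. RRM, KH, DEAD) and membership
in five RNA-process function classes (splicing, stability, transport,
modification, translation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FUNCTION_CLASSES",
    "EXCLUSION_REASONS",
    "RBPEntry",
    "RBPCatalog",
    "load_canonical_domains",
    "normalize_symbol",
    "compile_catalog",
    "annotate_rbds",
    "assign_function_classes",
    "tally_rbd_frequencies",
]

#: The five RNA-related process classes used for functional annotation.
FUNCTION_CLASSES = frozenset(
    {"splicing", "stability", "transport", "modification", "translation"}
)

#: Valid curation-flag reasons, in precedence order (highest first).
EXCLUSION_REASONS = ("histone", "contaminant", "mitochondrial")

_REASON_RANK = {r: i for i, r in enumerate(EXCLUSION_REASONS)}


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol: strip whitespace, uppercase.

    Aliases are deliberately not resolved; the catalogue is
    self-contained and uses symbol identity only.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


def load_canonical_domains() -> frozenset[str]:
    """Return the packaged set of canonical RNA-binding domain names.

    The list ships as an editable text file (one domain per line,
    ``#`` comments allowed) seeded with the classical RBDs: RRM, KH,
    DEAD-box, the CCCH/CCHC/C2H2/RanBP/metazoan zinc fingers, dsRBD,
    PUF, La, S1 and Helicase_C.
    """
    text = (
        resources.files("rbprofiler").joinpath("data/canonical_rbds.txt").read_text()
    )
    domains = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            domains.add(line)
    return frozenset(domains)


@dataclass(frozen=True)
class RBPEntry:
    """One putative RBP in the reference catalogue."""

    symbol: str
    sources: frozenset[str] = frozenset()
    excluded: bool = False
    exclusion_reason: str = "none"
    rbds: tuple[str, ...] = ()
    canonical_rbd: bool = False
    function_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty gene symbol")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError(
                f"{self.symbol}: excluded flag inconsistent with reason "
                f"{self.exclusion_reason!r}"
            )
        if self.canonical_rbd and not self.rbds:
            raise ValueError(f"{self.symbol}: canonical_rbd requires annotated RBDs")


@dataclass
class RBPCatalog:
    """A curated RBP reference catalogue.

    ``entries`` keeps every merged symbol, including curation-flagged
    ones; :meth:`curated` drops the flagged entries and is what the
    downstream analysis stages consume.
    """

    entries: dict[str, RBPEntry]
    canonical_domain_set: frozenset[str] = field(default_factory=load_canonical_domains)
    provenance: str = ""

    def __post_init__(self) -> None:
        for sym, entry in self.entries.items():
            if sym != entry.symbol:
                raise ValueError(f"key {sym!r} does not match entry {entry.symbol!r}")

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.entries

    def __getitem__(self, symbol: str) -> RBPEntry:
        return self.entries[normalize_symbol(symbol)]

    @property
    def symbols(self) -> set[str]:
        return set(self.entries)

    @property
    def n_merged(self) -> int:
        return len(self.entries)

    @property
    def n_flagged(self) -> int:
        return sum(e.excluded for e in self.entries.values())

    @property
    def n_curated(self) -> int:
        return self.n_merged - self.n_flagged

    def curated(self) -> "RBPCatalog":
        """Return the catalogue with curation-flagged entries removed."""
        kept = {s: e for s, e in self.entries.items() if not e.excluded}
        return RBPCatalog(kept, self.canonical_domain_set, self.provenance)

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.entries.values(), key=lambda e: e.symbol):
            rows.append(
                {
                    "symbol": e.symbol,
                    "sources": ";".join(sorted(e.sources)),
                    "excluded": e.excluded,
                    "exclusion_reason": e.exclusion_reason,
                    "rbds": ";".join(e.rbds),
                    "canonical_rbd": e.canonical_rbd,
                    "function_classes": ";".join(sorted(e.function_classes)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "symbol",
                "sources",
                "excluded",
                "exclusion_reason",
                "rbds",
                "canonical_rbd",
                "function_classes",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RBPCatalog":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        entries = {}
        for _, row in df.iterrows():
            e = RBPEntry(
                symbol=row["symbol"],
                sources=frozenset(s for s in str(row["sources"]).split(";") if s),
                excluded=bool(row["excluded"]) and str(row["excluded"]) != "False",
                exclusion_reason=row["exclusion_reason"] or "none",
                rbds=tuple(d for d in str(row["rbds"]).split(";") if d),
                canonical_rbd=bool(row["canonical_rbd"])
                and str(row["canonical_rbd"]) != "False",
                function_classes=frozenset(
                    c for c in str(row["function_classes"]).split(";") if c
                ),
            )
            entries[e.symbol] = e
        return cls(entries)


def _normalize_flags(
    flags: Mapping[str, str] | Iterable[tuple[str, str]] | None,
) -> dict[str, str]:
    """Collapse flags to one reason per symbol using precedence
    histone > contaminant > mitochondrial."""
    if flags is None:
        return {}
    pairs = flags.items() if isinstance(flags, Mapping) else flags
    out: dict[str, str] = {}
    for symbol, reason in pairs:
        if reason not in _REASON_RANK:
            raise ValueError(
                f"unknown exclusion reason {reason!r}; expected one of "
                f"{EXCLUSION_REASONS}"
            )
        sym = normalize_symbol(symbol)
        if sym not in out or _REASON_RANK[reason] < _REASON_RANK[out[sym]]:
            out[sym] = reason
    return out


def compile_catalog(
    experimental: Sequence[str],
    predicted: Sequence[str],
    flags: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
    provenance: str = "",
) -> RBPCatalog:
    """Merge experimental and predicted RBP lists into a catalogue.

    Entries are the case-normalized set union of both lists, with the
    origin(s) recorded per symbol. Symbols carrying a curation flag
    (histone / contaminant / mitochondrial) are marked excluded; flags
    naming symbols absent from the union are ignored with a warning.

    Returns the full catalogue (flagged entries included); call
    :meth:`RBPCatalog.curated` for the working list.
    """
    sources: dict[str, set[str]] = {}
    for label, symbols in (("experimental", experimental), ("predicted", predicted)):
        for s in symbols:
            sources.setdefault(normalize_symbol(s), set()).add(label)
    if not sources:
        raise ValueError("empty catalogue: no symbols in either source list")

    flag_map = _normalize_flags(flags)
    missing = sorted(set(flag_map) - set(sources))
    if missing:
        warnings.warn(
            f"{len(missing)} curation flag(s) name symbols absent from the "
            f"merged list and were ignored: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else ""),
            stacklevel=2,
        )
        for sym in missing:
            del flag_map[sym]

    entries = {}
    for sym in sorted(sources):
        reason = flag_map.get(sym, "none")
        entries[sym] = RBPEntry(
            symbol=sym,
            sources=frozenset(sources[sym]),
            excluded=reason != "none",
            exclusion_reason=reason,
        )
    return RBPCatalog(entries, provenance=provenance)


def annotate_rbds(
    catalog: RBPCatalog,
    domain_table: Mapping[str, Sequence[str]],
) -> RBPCatalog:
    """Attach RNA-binding domain annotations to every catalogue entry.

    Symbols absent from ``domain_table`` get an empty annotation and
    count as non-canonical. ``canonical_rbd`` is true iff the entry
    carries at least one domain from the catalogue's canonical set.
    """
    table = {normalize_symbol(s): tuple(doms) for s, doms in domain_table.items()}
    entries = {}
    for sym, e in catalog.entries.items():
        rbds = table.get(sym, ())
        canonical = bool(set(rbds) & catalog.canonical_domain_set)
        entries[sym] = replace(e, rbds=rbds, canonical_rbd=canonical)
    return RBPCatalog(entries, catalog.canonical_domain_set, catalog.provenance)


def assign_function_classes(
    catalog: RBPCatalog,
    class_table: Mapping[str, Iterable[str]],
) -> RBPCatalog:
    """Attach five-class RNA-process annotations to catalogue entries.

    Multi-class proteins keep every class ("every known RNA-related
    function of each individual RBP" counts). Entries absent from the
    table get the empty set and report downstream as "other".
    """
    table: dict[str, frozenset[str]] = {}
    for sym, classes in class_table.items():
        cls = frozenset(classes)
        unknown = cls - FUNCTION_CLASSES
        if unknown:
            raise ValueError(
                f"unknown function class label(s) {sorted(unknown)} for "
                f"{sym}; expected a subset of {sorted(FUNCTION_CLASSES)}"
            )
        table[normalize_symbol(sym)] = cls
    entries = {
        sym: replace(e, function_classes=table.get(sym, frozenset()))
        for sym, e in catalog.entries.items()
    }
    return RBPCatalog(entries, catalog.canonical_domain_set, catalog.provenance)


def tally_rbd_frequencies(
    catalog: RBPCatalog,
    detected: Iterable[str],
    mode: str = "presence",
) -> pd.DataFrame:
    """Tally RNA-binding domain frequencies among detected RBPs.

    Parameters
    ----------
    detected
        Symbols of detected RBPs; must all be in the catalogue.
    mode
        ``presence`` (default): an RBP contributes one count per
        distinct domain it carries. ``occurrence``: repeated copies of
        a domain in one protein each count.

    Returns
    -------
    DataFrame with columns ``domain``, ``count``, ``fraction``
    (denominator = number of detected RBPs), sorted by count
    descending, ties alphabetical.
    """
    if mode not in ("presence", "occurrence"):
        raise ValueError(f"unknown RBD count mode {mode!r}")
    detected = {normalize_symbol(s) for s in detected}
    if not detected:
        raise ValueError("empty detected set")
    missing = detected - catalog.symbols
    if missing:
        raise ValueError(
            f"detected symbols absent from catalogue: {sorted(missing)[:5]}"
        )
    counts: dict[str, int] = {}
    for sym in detected:
        rbds = catalog.entries[sym].rbds
        domains = set(rbds) if mode == "presence" else rbds
        for d in domains:
            counts[d] = counts.get(d, 0) + 1
    n = len(detected)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(d, c, c / n) for d, c in rows], columns=["domain", "count", "fraction"]
    )
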