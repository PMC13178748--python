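"""Reading seed lists and interaction tables into normalized records.

Identifiers are HGNC-style gene symbols, uppercased at parse time;
interaction confidences are unitless combined scores in [0, 1].  STRING
flat files print scores as integers in 0-999 (per-mille scale), while
API payloads use 0-1 reals; the scale is always an explicit argument,
never guessed, because a 0.9-vs-900 confusion silently empties a
network after thresholding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Protocol, TextIO

from .errors import MalformedInputError, SourceUnavailableError

ScoreScale = Literal["unit", "per_mille"]

#: Default high-confidence cut-off on the combined score (inclusive).
DEFAULT_SCORE_THRESHOLD = 0.700


def normalize_symbol(raw: str, line_number: int | None = None) -> str:
    """Uppercase a gene symbol, rejecting empty or whitespace-bearing tokens."""
    sym = raw.strip()
    if not sym:
        raise MalformedInputError("empty gene symbol", line_number)
    if any(ch.isspace() for ch in sym):
        raise MalformedInputError(
            f"gene symbol {raw!r} contains whitespace", line_number
        )
    return sym.upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One score-annotated undirected protein pair.

    The pair is unordered: equality and hashing ignore endpoint order.
    """

    a: str
    b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-interaction {self.a!r} is not a valid record")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(
                f"combined score {self.combined_score!r} outside [0, 1]"
            )

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (lexicographically sorted) endpoint pair."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionRecord):
            return NotImplemented
        return self.pair == other.pair and self.combined_score == other.combined_score

    def __hash__(self) -> int:
        return hash((self.pair, self.combined_score))


def read_seed_list(stream: TextIO | Iterable[str]) -> list[str]:
    """Read a plain-text seed list: one symbol per line, ``#`` comments.

    Symbols are uppercased; duplicates are dropped keeping the first
    occurrence, preserving file order.
    """
    seen: set[str] = set()
    out: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        sym = normalize_symbol(token, lineno)
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def parse_interactions_tsv(
    stream: TextIO | Iterable[str], score_scale: ScoreScale
) -> list[InteractionRecord]:
    """Parse a STRING-dialect interaction table.

    Expects tab-separated rows with at least (name_a, name_b, score).
    An optional header row is detected by a non-numeric score field; a
    header carrying a ``combined_score`` column (the STRING
    "protein links detailed" dialect) selects that column as the score.
    Self-pairs are dropped; with ``score_scale="per_mille"`` scores are
    divided by 1000.
    """
    if score_scale not in ("unit", "per_mille"):
        raise ValueError(f"unknown score scale {score_scale!r}")
    records: list[InteractionRecord] = []
    score_col = 2
    header_seen = False
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MalformedInputError(
                f"expected >= 3 tab-separated fields, got {len(fields)}", lineno
            )
        if not header_seen:
            header_seen = True
            if "combined_score" in fields:
                score_col = fields.index("combined_score")
                continue
            if not _is_number(fields[score_col]):
                continue  # plain header row
        raw_score = fields[score_col]
        if not _is_number(raw_score):
            raise MalformedInputError(f"non-numeric score {raw_score!r}", lineno)
        score = float(raw_score)
        if score_scale == "per_mille":
            score /= 1000.0
        if not 0.0 <= score <= 1.0:
            raise MalformedInputError(
                f"score {raw_score!r} outside [0, 1] after {score_scale} scaling",
                lineno,
            )
        a = normalize_symbol(fields[0], lineno)
        b = normalize_symbol(fields[1], lineno)
        if a == b:
            continue
        records.append(InteractionRecord(a, b, score))
    return records


def write_interactions_tsv(
    records: Iterable[InteractionRecord],
    stream: TextIO,
    score_scale: ScoreScale = "unit",
) -> None:
    """Write records in the same dialect :func:`parse_interactions_tsv` reads.

    Order-preserving; ``per_mille`` rounds to the nearest integer score.
    """
    stream.write("name_a\tname_b\tscore\n")
    for rec in records:
        if score_scale == "per_mille":
            stream.write(f"{rec.a}\t{rec.b}\t{round(rec.combined_score * 1000)}\n")
        else:
            stream.write(f"{rec.a}\t{rec.b}\t{rec.combined_score!r}\n")


def filter_by_score(
    records: Iterable[InteractionRecord], threshold: float
) -> list[InteractionRecord]:
    """Keep records with combined score >= threshold (inclusive), in order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold!r} outside [0, 1]")
    return [r for r in records if r.combined_score >= threshold]


class InteractionProvider(Protocol):
    """Anything that can return interaction rows for a seed set."""

    def fetch(self, seeds: list[str]) -> list[InteractionRecord]: ...


@dataclass
class FileProvider:
    """Offline provider backed by a STRING-dialect TSV file."""

    path: str
    score_scale: ScoreScale

    def fetch(self, seeds: list[str]) -> list[InteractionRecord]:
        try:
            with open(self.path, encoding="utf-8") as fh:
                return parse_interactions_tsv(fh, self.score_scale)
        except OSError as exc:
            raise SourceUnavailableError(
                f"cannot read interaction file {self.path!r}: {exc}"
            ) from exc


@dataclass
class InMemoryProvider:
    """Provider over an in-memory record list (synthetic fixtures, tests)."""

    records: list[InteractionRecord] = field(default_factory=list)

    def fetch(self, seeds: list[str]) -> list[InteractionRecord]:
        return list(self.records)


class StringApiProvider:
    """Live STRING REST provider (optional; requires the `requests` package).

    Query parameters are kept on :attr:`last_request_params` so the run
    log can record them verbatim for provenance.  The network type
    (functional vs physical) is an explicit option.
    """

    BASE_URL = "https://string-db.org/api/json/network"

    def __init__(
        self,
        species: int = 9606,
        required_score: int = 700,
        network_type: str = "functional",
        base_url: str | None = None,
    ):
        self.species = species
        self.required_score = required_score
        self.network_type = network_type
        self.base_url = base_url or self.BASE_URL
        self.last_request_params: dict | None = None

    def fetch(self, seeds: list[str]) -> list[InteractionRecord]:
        try:
            import requests
        except ImportError as exc:
            raise SourceUnavailableError(
                "live STRING queries need the 'requests' package"
            ) from exc
        params = {
            "identifiers": "%0d".join(seeds),
            "species": self.species,
            "required_score": self.required_score,
            "network_type": self.network_type,
        }
        self.last_request_params = dict(params)
        try:
            resp = requests.get(self.base_url, params=params, timeout=60)
            resp.raise_for_status()
            payload = resp.json()
        except Exception as exc:  # network failure, not an empty result
            raise SourceUnavailableError(f"STRING API request failed: {exc}") from exc
        records = []
        for row in payload:
            a = normalize_symbol(str(row["preferredName_A"]))
            b = normalize_symbol(str(row["preferredName_B"]))
            if a != b:
                records.append(InteractionRecord(a, b, float(row["score"])))
        return records


def _limit_partners(
    records: list[InteractionRecord],
    seeds: set[str],
    max_partners_per_seed: int,
) -> list[InteractionRecord]:
    """Keep, per seed, only its top-scoring partners (score desc, symbol asc)."""
    ranked: dict[str, list[tuple[float, str]]] = {s: [] for s in seeds}
    for rec in records:
        for u, v in ((rec.a, rec.b), (rec.b, rec.a)):
            if u in seeds and v not in seeds:
                ranked[u].append((-rec.combined_score, v))
    allowed: set[str] = set()
    for s, partners in ranked.items():
        for _, v in sorted(set(partners))[:max_partners_per_seed]:
            allowed.add(v)
    kept = []
    for rec in records:
        ok_a = rec.a in seeds or rec.a in allowed
        ok_b = rec.b in seeds or rec.b in allowed
        if ok_a and ok_b:
            kept.append(rec)
    return kept


def fetch_first_shell(
    seeds: list[str],
    source: InteractionProvider,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    max_partners_per_seed: int | None = None,
) -> list[InteractionRecord]:
    """Score-filtered interactions among seeds and their direct partners.

    The provider contract is that it returns rows among the seeds and
    their direct partners for this seed set, so every non-seed endpoint
    it returns is a first-shell partner; a record survives when at least
    one endpoint is a seed or both endpoints are such partners (for a
    conforming provider this reduces to the score filter).  File-backed
    providers are deterministic; provider failures surface as
    :class:`~ppinet.errors.SourceUnavailableError`.
    """
    if not seeds:
        return []
    seed_set = set(seeds)
    records = filter_by_score(source.fetch(list(seeds)), threshold)
    if max_partners_per_seed is not None:
        records = _limit_partners(records, seed_set, max_partners_per_seed)
    partners = {u for rec in records for u in rec.pair if u not in seed_set}
    kept = []
    for rec in records:
        seed_incident = rec.a in seed_set or rec.b in seed_set
        shell_internal = rec.a in partners and rec.b in partners
        if seed_incident or shell_internal:
            kept.append(rec)
    return kept


def records_from_text(text: str, score_scale: ScoreScale) -> list[InteractionRecord]:
    """Convenience wrapper: parse a TSV table held in a string."""
    return parse_interactions_tsv(io.StringIO(text), score_scale)
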