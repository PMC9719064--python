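"""Paired-corpus I/O and corpus-level evaluation reports.

The canonical on-disk format is JSONL with one record per complex/simple
pair and the fixed field names ``id``, ``source``, ``reference`` and
(optionally) ``generated``.  Plain-text parallel files
(``source.txt`` / ``reference.txt`` / ``generated.txt``, one paragraph per
line) are also accepted.  :func:`evaluate` aggregates readability,
ROUGE/SARI and reward statistics over a corpus into a reproducible report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import text_metrics as tm
from .rewards import RewardScorer

__all__ = [
    "PairRecord",
    "read_pairs",
    "write_pairs",
    "EvalConfig",
    "EvaluationReport",
    "evaluate",
]


@dataclass(frozen=True)
class PairRecord:
    """One complex/simple paragraph pair, optionally with a generated text."""

    id: str
    source: str
    reference: str
    generated: str | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.reference:
            raise ValueError("source and reference must be non-empty")


def _record_from_json(obj: dict, lineno: int, default_id: str) -> PairRecord:
    for key in ("source", "reference"):
        if key not in obj or not isinstance(obj[key], str) or not obj[key]:
            raise ValueError(
                f"line {lineno}: record missing non-empty string field {key!r}"
            )
    return PairRecord(
        id=str(obj.get("id", default_id)),
        source=obj["source"],
        reference=obj["reference"],
        generated=obj.get("generated"),
    )


def _read_jsonl(path: Path) -> list[PairRecord]:
    records: list[PairRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON ({exc.msg})") from None
            if not isinstance(obj, dict):
                raise ValueError(f"line {lineno}: record is not a JSON object")
            record = _record_from_json(obj, lineno, default_id=f"{lineno - 1:04d}")
            if record.id in seen_ids:
                raise ValueError(f"line {lineno}: duplicate id {record.id!r}")
            seen_ids.add(record.id)
            records.append(record)
    return records


def _read_parallel(directory: Path) -> list[PairRecord]:
    src_path = directory / "source.txt"
    ref_path = directory / "reference.txt"
    gen_path = directory / "generated.txt"
    if not src_path.exists() or not ref_path.exists():
        raise FileNotFoundError(
            f"parallel format requires {src_path} and {ref_path}"
        )
    sources = src_path.read_text(encoding="utf-8").splitlines()
    references = ref_path.read_text(encoding="utf-8").splitlines()
    generated: list[str] | None = None
    if gen_path.exists():
        generated = gen_path.read_text(encoding="utf-8").splitlines()
    if len(sources) != len(references):
        raise ValueError(
            f"line count mismatch: {len(sources)} sources vs "
            f"{len(references)} references"
        )
    if generated is not None and len(generated) != len(sources):
        raise ValueError(
            f"line count mismatch: {len(sources)} sources vs "
            f"{len(generated)} generated"
        )
    records = []
    for i, (src, ref) in enumerate(zip(sources, references)):
        if not src or not ref:
            raise ValueError(f"line {i + 1}: empty source or reference")
        records.append(
            PairRecord(
                id=f"{i:04d}",
                source=src,
                reference=ref,
                generated=generated[i] if generated is not None else None,
            )
        )
    return records


def read_pairs(path: str | Path, format: str = "jsonl") -> list[PairRecord]:
    """Read a paired corpus; order-preserving, ids auto-assigned when absent.

    ``format`` is "jsonl" (one JSON object per line) or "parallel" (a
    directory holding source.txt / reference.txt and optionally
    generated.txt).
    """
    path = Path(path)
    if format == "jsonl":
        if not path.exists():
            raise FileNotFoundError(path)
        records = _read_jsonl(path)
    elif format == "parallel":
        records = _read_parallel(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not records:
        raise ValueError(f"{path}: empty corpus")
    return records


def write_pairs(records: Iterable[PairRecord], path: str | Path) -> None:
    """Write records as canonical JSONL (stable key order, UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {"id": rec.id, "source": rec.source, "reference": rec.reference}
            if rec.generated is not None:
                obj["generated"] = rec.generated
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


@dataclass(frozen=True)
class EvalConfig:
    """Configuration echoed into every evaluation report."""

    fkgl_coefficients: str | tuple[float, float, float] = "standard"
    readability_only: bool = False
    scorer: RewardScorer | None = None
    seed: int | None = None

    def echo(self) -> dict:
        out: dict = {
            "fkgl_coefficients": list(self.fkgl_coefficients)
            if not isinstance(self.fkgl_coefficients, str)
            else self.fkgl_coefficients,
            "readability_only": self.readability_only,
            "seed": self.seed,
        }
        if self.scorer is not None:
            out["reward_weights"] = list(self.scorer.weights.as_tuple())
            out["delta_z_saturation"] = self.scorer.saturation
        return out


@dataclass
class EvaluationReport:
    """Corpus-level means; every mean carries the n it was computed over."""

    metrics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def add(self, name: str, values: Sequence[float]) -> None:
        values = list(values)
        if values:
            self.metrics[name] = {
                "mean": sum(values) / len(values),
                "n": len(values),
            }

    def to_json(self) -> str:
        return json.dumps(
            {"metrics": self.metrics, "config": self.config},
            indent=2,
            sort_keys=True,
        )

    def to_text(self) -> str:
        width = max((len(k) for k in self.metrics), default=10)
        lines = [f"{'metric':<{width}}  {'mean':>10}  {'n':>5}"]
        for name in sorted(self.metrics):
            entry = self.metrics[name]
            lines.append(f"{name:<{width}}  {entry['mean']:>10.4f}  {entry['n']:>5}")
        return "\n".join(lines)


def evaluate(pairs: Sequence[PairRecord], config: EvalConfig | None = None) -> EvaluationReport:
    """Readability / generation-metric / reward means over a paired corpus.

    Readability of the source and reference sides is always reported.
    Generation metrics (ROUGE-1/2 F1, SARI, generated-side readability, and
    rewards when a scorer is configured) cover the pairs that carry a
    generated text; requesting them on a corpus with none is an error
    unless ``readability_only`` is set.
    """
    if not pairs:
        raise ValueError("cannot evaluate an empty corpus")
    config = config or EvalConfig()
    with_generated = [p for p in pairs if p.generated is not None]
    if not with_generated and not config.readability_only:
        raise ValueError(
            "no pair has generated text; pass readability_only=True for a "
            "readability-only report"
        )

    report = EvaluationReport(config=config.echo())
    coeffs = config.fkgl_coefficients

    def _grades(texts: Iterable[str]) -> tuple[list[float], list[float]]:
        fkgls, aris = [], []
        for text in texts:
            stats = tm.analyze_text(text)
            if stats.n_words == 0 or stats.n_sentences == 0:
                continue
            fkgls.append(tm.fkgl(stats, coeffs))
            aris.append(tm.ari(stats))
        return fkgls, aris

    src_fkgl, src_ari = _grades(p.source for p in pairs)
    ref_fkgl, ref_ari = _grades(p.reference for p in pairs)
    report.add("fkgl_source", src_fkgl)
    report.add("ari_source", src_ari)
    report.add("fkgl_reference", ref_fkgl)
    report.add("ari_reference", ref_ari)

    if with_generated:
        gen_fkgl, gen_ari = _grades(p.generated for p in with_generated)
        report.add("fkgl_generated", gen_fkgl)
        report.add("ari_generated", gen_ari)
        report.add(
            "rouge1_f1",
            [tm.rouge_n(p.generated, p.reference, 1).f1 for p in with_generated],
        )
        report.add(
            "rouge2_f1",
            [tm.rouge_n(p.generated, p.reference, 2).f1 for p in with_generated],
        )
        report.add(
            "sari",
            [tm.sari(p.source, p.generated, [p.reference]) for p in with_generated],
        )
        if config.scorer is not None:
            breakdowns = [
                config.scorer.score(p.source, p.reference, p.generated)
                for p in with_generated
            ]
            report.add("r_cosine", [b.r_cosine for b in breakdowns])
            report.add("r_flesch", [b.r_flesch for b in breakdowns])
            report.add("r_lexical", [b.r_lexical for b in breakdowns])
            report.add("reward_total", [b.total for b in breakdowns])
            from .rewards import lexical_stats

            report.add(
                "delta_z",
                [
                    lexical_stats(p.source, p.generated, config.scorer.lexicon).delta_z
                    for p in with_generated
                ],
            )
    return report
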