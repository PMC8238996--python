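"""Machine-readable sample reports and batch summaries."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .genotyper import (
    CALL_DETECTED,
    CALL_SUSPECTED,
    GenotypeCall,
    JunctionCounts,
)

POSITIVE_CALLS_DEFAULT = (CALL_DETECTED, CALL_SUSPECTED)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class SampleReport:
    """One sample's screening result, serializable to JSON or a TSV row."""

    sample_id: str
    event_label: str
    counts: JunctionCounts
    vaf: float | None
    call: str
    parameters: dict = field(default_factory=dict)
    tool_version: str = __version__
    input_digests: dict = field(default_factory=dict)

    @classmethod
    def from_call(
        cls,
        sample_id: str,
        event_label: str,
        call: GenotypeCall,
        input_paths: Sequence[str | Path] = (),
    ) -> "SampleReport":
        return cls(
            sample_id=sample_id,
            event_label=event_label,
            counts=call.counts,
            vaf=call.vaf,
            call=call.call,
            parameters={
                "k_ref": call.k_ref,
                "k_alt": call.k_alt,
                "max_mismatch": call.max_mismatch,
                "search_revcomp": call.search_revcomp,
                "low_threshold": call.policy.low_threshold,
                "high_threshold": call.policy.high_threshold,
            },
            input_digests={str(p): file_digest(p) for p in input_paths},
        )

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "event_label": self.event_label,
            "counts": self.counts.as_dict(),
            "vaf": self.vaf,
            "call": self.call,
            "parameters": dict(self.parameters),
            "tool_version": self.tool_version,
            "input_digests": dict(self.input_digests),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SampleReport":
        return cls(
            sample_id=data["sample_id"],
            event_label=data["event_label"],
            counts=JunctionCounts(**data["counts"]),
            vaf=data["vaf"],
            call=data["call"],
            parameters=dict(data.get("parameters", {})),
            tool_version=data.get("tool_version", __version__),
            input_digests=dict(data.get("input_digests", {})),
        )


_TSV_COLUMNS = (
    "sample_id",
    "event_label",
    "mutant_reads",
    "wildtype_reads",
    "total_reads_scanned",
    "vaf",
    "call",
)


def _format_vaf(vaf: float | None) -> str:
    return "NA" if vaf is None else f"{vaf:.3f}"


def write_report(
    reports: SampleReport | Sequence[SampleReport],
    path: str | Path,
    format: str = "json",
) -> None:
    """Serialize report(s) to JSON (one object or a list) or TSV (one row each).

    Field order is fixed, so identical reports produce identical bytes; VAFs
    are printed to three decimals in TSV.
    """
    if isinstance(reports, SampleReport):
        many = [reports]
        single = True
    else:
        many = list(reports)
        single = False
    path = Path(path)
    if format == "json":
        payload = many[0].to_dict() if single else [r.to_dict() for r in many]
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for r in many:
            lines.append(
                "\t".join(
                    (
                        r.sample_id,
                        r.event_label,
                        str(r.counts.mutant_reads),
                        str(r.counts.wildtype_reads),
                        str(r.counts.total_reads_scanned),
                        _format_vaf(r.vaf),
                        r.call,
                    )
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> SampleReport:
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        raise ValueError(f"{path} holds a report list; expected a single report")
    return SampleReport.from_dict(data)


@dataclass
class BatchSummary:
    """Cohort positivity over a set of sample reports."""

    n_samples: int
    n_positive: int
    positivity_percent: float  # 100 * positives / samples, half-up to 1 decimal
    positive_calls: tuple = POSITIVE_CALLS_DEFAULT

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_positive": self.n_positive,
            "positivity_percent": self.positivity_percent,
            "positive_calls": list(self.positive_calls),
        }


def summarize_batch(
    reports: Iterable[SampleReport],
    positive_calls: Sequence[str] = POSITIVE_CALLS_DEFAULT,
) -> BatchSummary:
    """Count positive samples and compute positivity to one decimal (half-up).

    "Positive" defaults to detected-or-suspected calls: confirmed carriers can
    sit in the suspected VAF range on capture-based platforms.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("summarize_batch requires at least one report")
    positive_calls = tuple(positive_calls)
    n_positive = sum(1 for r in reports if r.call in positive_calls)
    percent = float(
        (Decimal(100 * n_positive) / Decimal(len(reports))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return BatchSummary(
        n_samples=len(reports),
        n_positive=n_positive,
        positivity_percent=percent,
        positive_calls=positive_calls,
    )
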