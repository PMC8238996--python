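"""Flat key-value (YAML) event configuration files.

An event file fully describes one insertion event so that a scan can be
reproduced without the reference FASTA it was built from::

    label: my-event
    contig: chr8
    position_1based: 55540494
    left_flank: ...ACGT...
    right_flank: ...ACGT...
    body: ...ACGT...        # or body_preset: aluy
    polya_len: 35
    tsd_len: 11

``body_preset: aluy`` substitutes the packaged 282-base AluY body.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .allele_model import InsertionEvent, build_event


class EventConfigError(ValueError):
    """An event configuration file is missing or malformed."""


def load_event(path: str | Path) -> InsertionEvent:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise EventConfigError(f"cannot parse event config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise EventConfigError(f"event config {path} is not a key-value mapping")
    body = data.get("body")
    if body is None and data.get("body_preset") == "aluy":
        from .presets import aluy_body

        body = aluy_body()
    required = ("contig", "position_1based", "left_flank", "right_flank")
    missing = [k for k in required if k not in data]
    if missing or body is None:
        if body is None:
            missing.append("body (or body_preset)")
        raise EventConfigError(f"event config {path} missing keys: {missing}")
    return build_event(
        contig=str(data["contig"]),
        position=int(data["position_1based"]),
        left_flank=str(data["left_flank"]).upper(),
        right_flank=str(data["right_flank"]).upper(),
        body=str(body).upper(),
        polya_len=int(data.get("polya_len", 0)),
        tsd_len=int(data.get("tsd_len", 0)),
        label=str(data.get("label", Path(path).stem)),
    )


def save_event(event: InsertionEvent, path: str | Path) -> None:
    data = {
        "label": event.label,
        "contig": event.contig,
        "position_1based": event.position_1based,
        "left_flank": event.left_flank,
        "right_flank": event.right_flank,
        "body": event.body,
        "polya_len": event.polya_len,
        "tsd_len": len(event.tsd),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
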