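"""Readers and writers for the delimited-text formats of the package.

There is no community standard for self-incompatibility cross tables, so
all tables are plain comma-separated text with a one-line header:

* **variety panel** — ``name,dsi_group,pasi_pair[,notation]``, one variety
  per line (``pasi_pair`` like ``R2R3``; the optional notation column is
  written canonically and validated on read);
* **cross records** — ``host,donor,outcome,method,n_fruit,n_flowers``, one
  observation per line, mirroring the one-line-per-observation layout of
  the published cross-outcome compilation;
* **orchard** — a small YAML document (variety shares, bloom windows,
  pollen production);
* **degradation config** — YAML with the :class:`~dssm.dsd.DsdConfig`
  fields.

All readers raise :class:`FileFormatError` naming the offending line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .genetics import (
    GenotypeError,
    VarietyGenotype,
    format_determinants,
    parse_genotype_notation,
)
from .inference import CrossRecord
from .dsd import DsdConfig
from .orchard import OrchardConfig, OrchardVariety

__all__ = [
    "FileFormatError",
    "read_panel",
    "write_panel",
    "read_records",
    "write_records",
    "read_orchard",
    "write_orchard",
    "read_dsd_config",
    "write_dsd_config",
]


class FileFormatError(ValueError):
    """Malformed input file; the message names the file and line."""


def _fail(path, lineno: int | None, msg: str) -> None:
    where = f"{path}" + (f", line {lineno}" if lineno else "")
    raise FileFormatError(f"{where}: {msg}")


def _split_pair(text: str) -> tuple[str, str]:
    alleles = [f"R{d}" for d in text.replace("R", "")]
    if len(alleles) != 2:
        raise GenotypeError(f"cannot read allele pair {text!r} (expected e.g. 'R2R3')")
    return alleles[0], alleles[1]


# -- variety panel ---------------------------------------------------------

_PANEL_FIELDS = ("name", "dsi_group", "pasi_pair")


def read_panel(path: str | Path) -> dict[str, VarietyGenotype]:
    """Read a variety panel; keys preserve file order."""
    path = Path(path)
    panel: dict[str, VarietyGenotype] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _PANEL_FIELDS if c not in (reader.fieldnames or [])]
        if missing:
            _fail(path, 1, f"missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            name = (row["name"] or "").strip()
            if not name:
                _fail(path, lineno, "empty variety name")
            if name in panel:
                _fail(path, lineno, f"duplicate variety name {name!r}")
            try:
                v = VarietyGenotype(
                    name=name,
                    dsi_group=(row["dsi_group"] or "").strip(),
                    pasi=_split_pair((row["pasi_pair"] or "").strip()),
                )
                notation = (row.get("notation") or "").strip()
                if notation:
                    parsed = parse_genotype_notation(notation, name=name)
                    if (parsed.dsi_group, parsed.pasi) != (v.dsi_group, v.pasi):
                        raise GenotypeError(
                            f"notation {notation!r} disagrees with columns "
                            f"{v.dsi_group}/{format_determinants(v.pasi)}"
                        )
            except GenotypeError as e:
                _fail(path, lineno, str(e))
            panel[name] = v
    return panel


def write_panel(panel: Mapping[str, VarietyGenotype], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*_PANEL_FIELDS, "notation"])
        for v in panel.values():
            writer.writerow(
                [v.name, v.dsi_group, format_determinants(v.pasi), v.notation]
            )


# -- cross records ---------------------------------------------------------

_RECORD_FIELDS = ("host", "donor", "outcome", "method", "n_fruit", "n_flowers")


def read_records(
    path: str | Path, panel: Mapping[str, VarietyGenotype] | None = None
) -> list[CrossRecord]:
    """Read cross records; with ``panel`` given, names are validated against it."""
    path = Path(path)
    records: list[CrossRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("host", "donor", "outcome") if c not in (reader.fieldnames or [])]
        if missing:
            _fail(path, 1, f"missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            host = (row["host"] or "").strip()
            donor = (row["donor"] or "").strip()
            if panel is not None:
                for n in (host, donor):
                    if n not in panel:
                        _fail(path, lineno, f"unknown variety name {n!r}")
            try:
                records.append(
                    CrossRecord(
                        host=host,
                        donor=donor,
                        outcome=(row["outcome"] or "").strip(),
                        method=(row.get("method") or "fruit_test").strip(),
                        selfing=host == donor,
                        n_fruit=int(row["n_fruit"]) if row.get("n_fruit") else None,
                        n_flowers=int(row["n_flowers"]) if row.get("n_flowers") else None,
                    )
                )
            except ValueError as e:
                _fail(path, lineno, str(e))
    return records


def write_records(records: Sequence[CrossRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RECORD_FIELDS)
        for r in records:
            writer.writerow(
                [
                    r.host,
                    r.donor,
                    r.outcome,
                    r.method,
                    "" if r.n_fruit is None else r.n_fruit,
                    "" if r.n_flowers is None else r.n_flowers,
                ]
            )


# -- orchard and degradation configs --------------------------------------


def read_orchard(path: str | Path) -> OrchardConfig:
    """Read an orchard description from YAML.

    Layout::

        season_length: 30
        flowers_per_variety: 100
        pollen_per_flower_per_day: 5.0
        varieties:
          - {name: Tanche, dsi_group: G2, pasi_pair: R2R3,
             proportion: 0.8, bloom_start: 5, bloom_end: 20}
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise FileFormatError(f"{path}: invalid YAML ({e})") from None
    if not isinstance(doc, dict) or "varieties" not in doc:
        _fail(path, None, "expected a mapping with a 'varieties' list")
    varieties = []
    for i, entry in enumerate(doc["varieties"], start=1):
        try:
            genotype = VarietyGenotype(
                name=str(entry["name"]),
                dsi_group=str(entry["dsi_group"]),
                pasi=_split_pair(str(entry["pasi_pair"])),
            )
            varieties.append(
                OrchardVariety(
                    genotype=genotype,
                    proportion=float(entry["proportion"]),
                    bloom_start=int(entry["bloom_start"]),
                    bloom_end=int(entry["bloom_end"]),
                )
            )
        except (KeyError, TypeError, ValueError, GenotypeError) as e:
            _fail(path, None, f"variety entry {i}: {e}")
    try:
        return OrchardConfig(
            varieties=tuple(varieties),
            flowers_per_variety=int(doc.get("flowers_per_variety", 100)),
            pollen_per_flower_per_day=float(doc.get("pollen_per_flower_per_day", 5.0)),
            season_length=int(doc.get("season_length", 30)),
        )
    except ValueError as e:
        raise FileFormatError(f"{path}: {e}") from None


def write_orchard(orchard: OrchardConfig, path: str | Path) -> None:
    doc = {
        "season_length": orchard.season_length,
        "flowers_per_variety": orchard.flowers_per_variety,
        "pollen_per_flower_per_day": orchard.pollen_per_flower_per_day,
        "varieties": [
            {
                "name": v.genotype.name,
                "dsi_group": v.genotype.dsi_group,
                "pasi_pair": format_determinants(v.genotype.pasi),
                "proportion": v.proportion,
                "bloom_start": v.bloom_start,
                "bloom_end": v.bloom_end,
            }
            for v in orchard.varieties
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_dsd_config(path: str | Path) -> DsdConfig:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        raise FileFormatError(f"{path}: invalid YAML ({e})") from None
    if not isinstance(doc, dict):
        _fail(path, None, "expected a mapping of DsdConfig fields")
    try:
        if "short_lived" in doc:
            doc["short_lived"] = frozenset(doc["short_lived"])
        return DsdConfig(**doc)
    except (TypeError, ValueError) as e:
        raise FileFormatError(f"{path}: {e}") from None


def write_dsd_config(config: DsdConfig, path: str | Path) -> None:
    doc = {
        "onset_day": config.onset_day,
        "full_day": config.full_day,
        "ovule_access_day_max": config.ovule_access_day_max,
        "short_lived": sorted(config.short_lived),
        "dsi_degradable": config.dsi_degradable,
        "mode": config.mode,
        "degradation_rate_per_day": dict(config.degradation_rate_per_day),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
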