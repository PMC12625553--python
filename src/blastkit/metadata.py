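"""Metadata harvesting from GenBank flat files and NCBI-style JSON reports.

Each input file yields one record. The default fields are accession,
organism, host, isolation_source and collection_region; ``--all`` adds every
source-feature qualifier seen across the batch. A missing value is always
reported as the literal string ``not_specified``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("blastkit")

NOT_SPECIFIED = "not_specified"
DEFAULT_FIELDS = ("accession", "organism", "host", "isolation_source", "collection_region")


class MetadataError(ValueError):
    """Raised for unusable metadata inputs."""


@dataclass
class MetadataRecord:
    """Harvested fields for one input file; missing values are filled on output."""

    source: str
    values: dict[str, str] = field(default_factory=dict)

    def get(self, fld: str) -> str:
        value = self.values.get(fld, "")
        return value if value else NOT_SPECIFIED


def _sniff_format(path: Path) -> str:
    """Content-based detection: a GenBank LOCUS line vs a JSON object."""
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("{", "[")):
                return "json"
            if stripped.startswith("LOCUS"):
                return "genbank"
            break
    raise MetadataError(f"{path} is neither a GenBank flat file nor JSON")


def _harvest_genbank(path: Path) -> dict[str, str]:
    values: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "genbank"):
        values.setdefault("accession", record.id)
        organism = record.annotations.get("organism", "")
        if organism:
            values.setdefault("organism", organism)
        for feat in record.features:
            if feat.type != "source":
                continue
            for key, vals in feat.qualifiers.items():
                if vals and key not in values:
                    values[key] = str(vals[0])
        break  # one record per file is the expected shape
    if not values:
        raise MetadataError(f"{path} parsed as GenBank but contained no records")
    values["collection_region"] = values.get("geo_loc_name") or values.get("country", "")
    return values


def _flatten_json(obj, prefix: str = "") -> dict[str, str]:
    flat: dict[str, str] = {}
    if isinstance(obj, dict):
        for key, val in obj.items():
            flat.update(_flatten_json(val, f"{prefix}{key}." if prefix else f"{key}."))
    elif isinstance(obj, list):
        # biosample attribute lists use {"name": ..., "value": ...} pairs
        for item in obj:
            if isinstance(item, dict) and "name" in item and "value" in item:
                flat[f"{prefix}{item['name']}"] = str(item["value"])
            else:
                flat.update(_flatten_json(item, prefix))
    else:
        flat[prefix.rstrip(".")] = str(obj)
    return flat


#: Leaf-key synonyms in NCBI assembly data reports, by harvested field name.
_JSON_KEYS = {
    "accession": ("accession", "currentAccession", "pairedAccession"),
    "organism": ("organismName", "organism", "sciName"),
    "host": ("host",),
    "isolation_source": ("isolation_source", "isolationSource"),
    "collection_region": ("geo_loc_name", "geoLocName", "country"),
}


def _harvest_json(path: Path) -> dict[str, str]:
    with open(path) as handle:
        payload = json.load(handle)
    if isinstance(payload, dict) and isinstance(payload.get("reports"), list) and payload["reports"]:
        payload = payload["reports"][0]
    flat = _flatten_json(payload)
    values: dict[str, str] = {}
    for out_field, keys in _JSON_KEYS.items():
        for full_key, val in flat.items():
            leaf = full_key.rsplit(".", 1)[-1]
            if leaf in keys and val:
                values[out_field] = val
                break
        else:
            continue
    # expose remaining leaves for --all
    for full_key, val in flat.items():
        leaf = full_key.rsplit(".", 1)[-1]
        values.setdefault(leaf, val)
    return values


def harvest_metadata(
    paths: str | Path, fields: Sequence[str] | None = None
) -> tuple[list[MetadataRecord], list[str]]:
    """Harvest one record per GenBank/JSON file.

    ``fields=None`` means ``--all``: the output field list is the default five
    plus every additional qualifier observed, union-ordered by first
    appearance. Unparseable files are skipped with a warning.
    """
    root = Path(paths)
    if root.is_dir():
        files = sorted(p for p in root.rglob("*") if p.is_file())
        if not files:
            raise MetadataError(f"directory {root} is empty")
    elif root.exists():
        files = [root]
    else:
        raise MetadataError(f"input path does not exist: {root}")

    records: list[MetadataRecord] = []
    seen_fields: list[str] = list(DEFAULT_FIELDS)
    for path in files:
        try:
            kind = _sniff_format(path)
            values = _harvest_genbank(path) if kind == "genbank" else _harvest_json(path)
        except (MetadataError, ValueError) as exc:
            logger.warning("skipping unparseable metadata file %s: %s", path, exc)
            continue
        records.append(MetadataRecord(source=path.name, values=values))
        for key in values:
            if key not in seen_fields:
                seen_fields.append(key)
    if not records:
        raise MetadataError(f"no parseable GenBank/JSON files under {paths}")

    out_fields = list(fields) if fields is not None else seen_fields
    return records, out_fields


def metadata_frame(records: Iterable[MetadataRecord], fields: Sequence[str]) -> pd.DataFrame:
    rows = [{"file": r.source, **{f: r.get(f) for f in fields}} for r in records]
    return pd.DataFrame(rows, columns=["file", *fields])


def write_metadata(
    records: Sequence[MetadataRecord],
    fields: Sequence[str],
    fmt: str,
    out: str | Path,
) -> Path:
    """Emit the records as CSV, TSV or JSON; round-trip safe."""
    if not records:
        raise MetadataError("no records to write")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    frame = metadata_frame(records, fields)
    if fmt == "csv":
        frame.to_csv(out, index=False)
    elif fmt == "tsv":
        frame.to_csv(out, index=False, sep="\t")
    elif fmt == "json":
        out.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        raise MetadataError(f"unsupported output format {fmt!r} (csv, tsv, json)")
    return out
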