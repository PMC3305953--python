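"""Reading and writing the pipeline's flat-file formats (CSV, YAML, JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .natural_history import NaturalHistoryParams


def write_params(params: NaturalHistoryParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def read_params(path) -> NaturalHistoryParams:
    with open(path) as fh:
        return NaturalHistoryParams.from_dict(yaml.safe_load(fh))


def write_manifest(path, **entries) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
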