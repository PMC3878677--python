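"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: tab-separated tables with a header row (UTF-8),
JSON reports, rule-set text files, and SIF / GraphML network exports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .ensemble_mining import PairNetwork, ProteinRanking
from .quantify import SampleQuantMatrix
from .rule_learner import RuleSet, parse_ruleset, serialize_ruleset


# ---------------------------------------------------------------------------
# tables


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Labels table with columns sample_id, class[, subject]."""
    df = read_table(path)
    missing = {"sample_id", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"labels file {path} lacks columns {sorted(missing)}")
    return df


def labels_mapping(labels: pd.DataFrame) -> dict[str, str]:
    return dict(zip(labels["sample_id"], labels["class"]))


# ---------------------------------------------------------------------------
# matrices


def write_matrix(m: SampleQuantMatrix, path: str | Path) -> None:
    """Wide TSV (rows = ``accession|score_type`` features, columns =
    samples) plus a JSON sidecar with labels and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wide = m.scores.copy()
    wide.insert(0, "feature", wide.index)
    wide.to_csv(path, sep="\t", index=False, encoding="utf-8")
    sidecar = {
        "labels": {s: m.labels[s] for s in m.samples},
        "provenance": m.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, ensure_ascii=False), encoding="utf-8")


def read_matrix(path: str | Path) -> SampleQuantMatrix:
    path = Path(path)
    wide = pd.read_csv(path, sep="\t", encoding="utf-8")
    wide = wide.set_index("feature")
    wide.index.name = None
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8"))
    labels = pd.Series(sidecar["labels"], name="class")
    return SampleQuantMatrix(scores=wide, labels=labels,
                             provenance=sidecar.get("provenance", str(path)))


# ---------------------------------------------------------------------------
# rule sets


def write_ruleset(rs: RuleSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(serialize_ruleset(rs), encoding="utf-8")


def read_ruleset(path: str | Path) -> RuleSet:
    return parse_ruleset(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# rankings and networks


def write_ranking(ranking: ProteinRanking, out_dir: str | Path) -> list[Path]:
    """One TSV per class: rank, feature, count, share."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for cls, rows in sorted(ranking.per_class.items()):
        df = pd.DataFrame(
            [{"rank": i + 1, "feature": feat, "count": count,
              "share": round(share, 4)}
             for i, (feat, count, share) in enumerate(rows)])
        path = out_dir / f"ranking_{_safe_name(cls)}.tsv"
        df.to_csv(path, sep="\t", index=False, encoding="utf-8")
        written.append(path)
    return written


def write_sif(net: PairNetwork, path: str | Path) -> None:
    """Simple interaction format: ``featureA<TAB>pair_<class><TAB>featureB``."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{a}\tpair_{_safe_name(cls)}\t{b}" for a, b, cls, _ in net.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def write_graphml(net: PairNetwork, path: str | Path) -> None:
    """GraphML export with class, count, and per-class colour edge
    attributes, ready for Cytoscape-style viewers."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.to_networkx(), str(path), encoding="utf-8")


def _safe_name(name: str) -> str:
    return "".join(ch if (ch.isalnum() or ch in "-_+") else "_" for ch in name)


# ---------------------------------------------------------------------------
# reports


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, ensure_ascii=False),
                          encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
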