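"""Library annotation and 12-class classification of aligned features.

Consensus spectra are matched against a reference library by plain cosine
similarity on the unit-mass grid; the best hit is kept when its score
reaches the minimum cosine (default 0.7). Annotated compound names are then
mapped onto compound classes through the user-supplied class library, with
everything unmatched falling into an explicit "unclassified" pool.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedFeature
from .errors import ParameterError
from .similarity import cosine, cosine_matrix  # noqa: F401  (re-exported API)
from .spectra_io import ClassLibrary, LibraryEntry

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Annotation:
    """Best library match (or none) and compound class for one node."""

    node_id: str
    compound: str | None = None
    score: float = 0.0
    compound_class: str = UNCLASSIFIED
    tie: bool = False  # best score shared by >1 library entry


def annotate(
    nodes: Sequence[AlignedFeature],
    library: Sequence[LibraryEntry],
    min_cosine: float = 0.7,
) -> list[Annotation]:
    """Best-scoring library hit per node, kept only at score >= min_cosine.

    Ties at the best score are broken by library order and flagged on the
    annotation. Nodes whose best score falls below the threshold stay
    unannotated (compound ``None``).
    """
    if not library:
        raise ParameterError("library must be non-empty")
    if not 0 < min_cosine <= 1:
        raise ParameterError("min_cosine must be in (0, 1]")
    if not nodes:
        return []
    scores = cosine_matrix([n.consensus_spectrum for n in nodes],
                           [e.spectrum for e in library])
    out: list[Annotation] = []
    for i, node in enumerate(nodes):
        best = int(np.argmax(scores[i]))  # argmax keeps the first = library order
        s = float(scores[i, best])
        tie = bool(np.sum(np.isclose(scores[i], s, rtol=0, atol=1e-12)) > 1)
        if s >= min_cosine:
            out.append(Annotation(node.node_id, library[best].name, s,
                                  UNCLASSIFIED, tie))
        else:
            out.append(Annotation(node.node_id, None, s, UNCLASSIFIED, tie))
    return out


def assign_classes(
    annotations: Sequence[Annotation], classes: ClassLibrary
) -> list[Annotation]:
    """Map annotated compound names to classes; order preserved, idempotent.

    Compounds absent from the class library, and unannotated nodes, receive
    the explicit "unclassified" label.
    """
    out = []
    for ann in annotations:
        cls = classes.lookup(ann.compound) if ann.compound else None
        out.append(replace(ann, compound_class=cls or UNCLASSIFIED))
    return out


def annotation_table(
    annotations: Sequence[Annotation],
    nodes: Sequence[AlignedFeature] | None = None,
) -> pd.DataFrame:
    """Exportable annotation table; per-sample heights joined when nodes given."""
    rows = []
    by_id = {n.node_id: n for n in nodes} if nodes else {}
    for ann in annotations:
        row: dict[str, object] = {
            "node_id": ann.node_id,
            "compound": ann.compound if ann.compound is not None else "",
            "cosine": ann.score,
            "class": ann.compound_class,
        }
        node = by_id.get(ann.node_id)
        if node is not None:
            row["rt_min"] = node.rt
            for sid, h in sorted(node.per_sample_height.items()):
                row[f"height_{sid}"] = h
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotations(
    annotations: Sequence[Annotation],
    path: str | Path,
    nodes: Sequence[AlignedFeature] | None = None,
) -> None:
    annotation_table(annotations, nodes).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path, dtype={"node_id": str}, keep_default_na=False)
    return [
        Annotation(
            node_id=str(r["node_id"]),
            compound=str(r["compound"]) or None,
            score=float(r["cosine"]),
            compound_class=str(r["class"]) or UNCLASSIFIED,
        )
        for _, r in df.iterrows()
    ]
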