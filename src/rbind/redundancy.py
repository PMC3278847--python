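"""Feature-vector-based redundancy reduction of training data.

Two feature vectors are redundant only when both their element values and
their binding labels coincide; one representative (the first seen) is kept.
Vectors with identical values but opposite labels are "common vectors" and
both are retained, since discarding either would lose binding information
that sequence-similarity filtering throws away wholesale.  Values are
rounded to a fixed number of decimals before comparison so equality is
reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .encoding import FeatureVector

__all__ = ["DedupedDataset", "dedupe", "common_vectors"]


@dataclass
class DedupedDataset:
    vectors: list[FeatureVector]
    n_pos: int
    n_neg: int
    n_common: int
    precision: int

    def __len__(self) -> int:
        return len(self.vectors)

    def summary(self) -> dict:
        return {"n_pos": self.n_pos, "n_neg": self.n_neg,
                "n_total": len(self.vectors), "n_common": self.n_common,
                "precision": self.precision}

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def _value_key(vector: FeatureVector, precision: int) -> tuple:
    return tuple(round(float(x), precision) for x in vector.values)


def dedupe(vectors: list[FeatureVector], precision: int = 6) -> DedupedDataset:
    """Keep the first vector per (rounded values, label) key.

    Label-discordant vectors sharing one value key are all single
    representatives of their own (values, label) class and are retained;
    ``n_common`` counts the distinct value keys seen with both labels.
    """
    widths = {v.values.shape[0] for v in vectors}
    if len(widths) > 1:
        raise ValueError(f"vectors with mixed schemas: lengths {sorted(widths)}")

    kept: list[FeatureVector] = []
    seen: set[tuple] = set()
    labels_by_key: dict[tuple, set[int]] = {}
    for v in vectors:
        key = _value_key(v, precision)
        labels_by_key.setdefault(key, set()).add(v.label)
        if (key, v.label) not in seen:
            seen.add((key, v.label))
            kept.append(v)

    n_pos = sum(1 for v in kept if v.label == 1)
    n_neg = len(kept) - n_pos
    n_common = sum(1 for labs in labels_by_key.values() if len(labs) == 2)
    return DedupedDataset(vectors=kept, n_pos=n_pos, n_neg=n_neg,
                          n_common=n_common, precision=precision)


def common_vectors(vectors: list[FeatureVector], precision: int = 6) -> int:
    """Number of distinct value keys that occur with both binding labels."""
    labels_by_key: dict[tuple, set[int]] = {}
    for v in vectors:
        labels_by_key.setdefault(_value_key(v, precision), set()).add(v.label)
    return sum(1 for labs in labels_by_key.values() if len(labs) == 2)
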