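"""Binary response data: the container every other module consumes.

A :class:`ResponseMatrix` holds a persons x items 0/1 endorsement matrix with
unique item labels and optional binary person covariates (e.g. sex, age group).
Missing data are handled by listwise deletion at load time only; downstream
operations require complete matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ResponseMatrix", "SampleSplit", "load_responses", "split_samples"]


@dataclass
class ResponseMatrix:
    """Persons x items binary responses with labels and optional covariates.

    Parameters
    ----------
    responses
        Integer array of shape ``(n_persons, n_items)``; every cell 0 or 1.
    item_labels
        Unique column labels, one per item.
    covariates
        Optional mapping of name -> binary integer vector of length
        ``n_persons``. Covariates are carried through subsetting but are used
        only by the differential-functioning operations.
    """

    responses: np.ndarray
    item_labels: list[str]
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValidationError("responses must be a 2-D persons x items array")
        bad = ~np.isin(self.responses, (0, 1))
        if bad.any():
            v, i = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at row {v}, column {self.item_labels[i] if i < len(self.item_labels) else i}: "
                f"{self.responses[v, i]!r}"
            )
        self.responses = self.responses.astype(np.int8)
        self.item_labels = list(self.item_labels)
        if len(self.item_labels) != self.responses.shape[1]:
            raise ValidationError(
                f"{len(self.item_labels)} labels for {self.responses.shape[1]} columns"
            )
        if len(set(self.item_labels)) != len(self.item_labels):
            dupes = {l for l in self.item_labels if self.item_labels.count(l) > 1}
            raise ValidationError(f"duplicate item labels: {sorted(dupes)}")
        for name, vec in self.covariates.items():
            vec = np.asarray(vec)
            if vec.shape != (self.n_persons,):
                raise ValidationError(
                    f"covariate {name!r} has length {vec.shape}, expected ({self.n_persons},)"
                )
            if len(np.unique(vec)) > 2:
                raise ValidationError(f"covariate {name!r} has more than 2 distinct values")
            self.covariates[name] = vec.astype(np.int8)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def raw_scores(self) -> np.ndarray:
        """Per-person total score (count of endorsed items)."""
        return self.responses.sum(axis=1)

    def subset_items(self, labels: list[str]) -> "ResponseMatrix":
        """Return a new matrix restricted to ``labels``, in the given order."""
        idx = [self.item_labels.index(l) for l in labels]
        return ResponseMatrix(
            self.responses[:, idx], list(labels), {k: v.copy() for k, v in self.covariates.items()}
        )

    def subset_persons(self, index: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            self.responses[index],
            list(self.item_labels),
            {k: v[index] for k, v in self.covariates.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_labels)
        for name, vec in self.covariates.items():
            df[name] = vec
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SampleSplit:
    """Two disjoint random subsamples (calibration / validation) of equal size."""

    calibration: ResponseMatrix
    validation: ResponseMatrix
    seed: int

    def __post_init__(self) -> None:
        if self.calibration.n_persons != self.validation.n_persons:
            raise ValidationError("calibration and validation samples must have equal size")


def load_responses(
    path,
    item_columns: list[str],
    covariate_columns: list[str] | None = None,
) -> ResponseMatrix:
    """Load a CSV of binary responses, dropping incomplete rows.

    Rows with any missing value among ``item_columns`` (or the requested
    covariates) are removed listwise; the count of dropped rows is logged and
    stored in the ``n_dropped`` attribute of the returned matrix.
    """
    covariate_columns = covariate_columns or []
    df = pd.read_csv(path)
    for col in list(item_columns) + list(covariate_columns):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not found in {path}")
    sub = df[list(item_columns) + list(covariate_columns)]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d incomplete rows from %s", n_dropped, path)
    sub = sub[complete]
    resp = sub[item_columns].to_numpy()
    bad = ~np.isin(resp, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary value {resp[r, c]!r} in column {item_columns[c]!r}, data row {sub.index[r]}"
        )
    rm = ResponseMatrix(
        resp.astype(np.int8),
        list(item_columns),
        {c: sub[c].to_numpy().astype(np.int8) for c in covariate_columns},
    )
    rm.n_dropped = n_dropped
    return rm


def split_samples(data: ResponseMatrix, n_per_sample: int, seed: int) -> SampleSplit:
    """Draw two disjoint simple random subsamples of ``n_per_sample`` persons each.

    Deterministic for a fixed seed. Raises if the population is too small.
    """
    if 2 * n_per_sample > data.n_persons:
        raise ValidationError(
            f"need at least {2 * n_per_sample} persons for two samples of "
            f"{n_per_sample}; have {data.n_persons}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_persons)
    cal = np.sort(perm[:n_per_sample])
    val = np.sort(perm[n_per_sample : 2 * n_per_sample])
    return SampleSplit(data.subset_persons(cal), data.subset_persons(val), seed)


def write_split(split: SampleSplit, out_dir) -> None:
    """Write calibration/validation CSVs plus a JSON metadata sidecar."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    split.calibration.to_csv(out / "calibration.csv")
    split.validation.to_csv(out / "validation.csv")
    meta = {
        "seed": split.seed,
        "n_per_sample": split.calibration.n_persons,
        "item_labels": split.calibration.item_labels,
    }
    (out / "split.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
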