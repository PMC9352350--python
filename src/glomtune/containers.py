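"""In-memory containers for glomerular response data and their text IO.

A :class:`ResponseDataset` bundles, for each imaged olfactory bulb (OB), a
glomerulus x odorant response matrix (dF/F), the 2-D centroid of each
glomerulus (mediolateral um from the midline, anteroposterior um from the
caudal sinus), per-glomerulus baseline fluorescence, and the OB / mouse
identity.  The odorant axis is identical across OBs so matrices can be
compared column-by-column.

Matrices are stored as pandas DataFrames (glomeruli as rows, odorants as
columns) and serialized as tab-delimited text plus a JSON sidecar carrying
the identity metadata and positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd


@dataclass
class OBResponse:
    """Responses and geometry of one olfactory bulb.

    ``responses``: DataFrame, glomerulus ids x odorant ids, dF/F (nonnegative
    after thresholding).  ``positions``: DataFrame indexed by glomerulus id
    with ``ml_um`` and ``ap_um`` columns.  ``baseline_f``: optional Series of
    per-glomerulus baseline fluorescence.
    """

    responses: pd.DataFrame
    positions: pd.DataFrame
    ob_id: str
    mouse_id: str
    baseline_f: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.positions.empty:
            missing = set(self.responses.index) - set(self.positions.index)
            if missing:
                raise ValueError(
                    f"OB {self.ob_id}: glomeruli without positions: {sorted(missing)[:5]}"
                )
            if not np.isfinite(
                self.positions.loc[self.responses.index, ["ml_um", "ap_um"]].to_numpy()
            ).all():
                raise ValueError(f"OB {self.ob_id}: non-finite glomerulus positions")

    @property
    def glomeruli(self) -> list[str]:
        return list(self.responses.index)

    @property
    def odorants(self) -> list[str]:
        return list(self.responses.columns)


@dataclass
class ResponseDataset:
    """A set of OBs imaged with the same odorant panel."""

    obs: list[OBResponse]

    def __post_init__(self) -> None:
        if self.obs:
            ref = self.obs[0].odorants
            for ob in self.obs[1:]:
                if ob.odorants != ref:
                    raise ValueError(
                        f"OB {ob.ob_id}: odorant axis differs from OB {self.obs[0].ob_id}"
                    )

    def __iter__(self) -> Iterator[OBResponse]:
        return iter(self.obs)

    def __len__(self) -> int:
        return len(self.obs)

    @property
    def odorants(self) -> list[str]:
        return self.obs[0].odorants if self.obs else []

    @property
    def mouse_ids(self) -> list[str]:
        return sorted({ob.mouse_id for ob in self.obs})

    def matrices(self) -> list[pd.DataFrame]:
        return [ob.responses for ob in self.obs]


def write_dataset(dataset: ResponseDataset, outdir: str | Path) -> list[Path]:
    """Write one ``<ob_id>.responses.tsv`` + ``<ob_id>.meta.json`` per OB."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for ob in dataset:
        mat_path = outdir / f"{ob.ob_id}.responses.tsv"
        ob.responses.to_csv(mat_path, sep="\t", index_label="glomerulus")
        meta = {
            "ob_id": ob.ob_id,
            "mouse_id": ob.mouse_id,
            "positions": {
                g: [float(ob.positions.loc[g, "ml_um"]), float(ob.positions.loc[g, "ap_um"])]
                for g in ob.positions.index
            },
            "baseline_f": None
            if ob.baseline_f is None
            else {g: float(v) for g, v in ob.baseline_f.items()},
        }
        meta_path = outdir / f"{ob.ob_id}.meta.json"
        meta_path.write_text(json.dumps(meta, indent=1), encoding="utf-8")
        written += [mat_path, meta_path]
    return written


def read_dataset(indir: str | Path) -> ResponseDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    indir = Path(indir)
    obs = []
    for mat_path in sorted(indir.glob("*.responses.tsv")):
        ob_id = mat_path.name.removesuffix(".responses.tsv")
        responses = pd.read_csv(mat_path, sep="\t", index_col="glomerulus")
        responses.index = responses.index.astype(str)
        meta = json.loads((indir / f"{ob_id}.meta.json").read_text(encoding="utf-8"))
        positions = pd.DataFrame.from_dict(
            meta["positions"], orient="index", columns=["ml_um", "ap_um"]
        )
        baseline = (
            pd.Series(meta["baseline_f"]) if meta.get("baseline_f") else None
        )
        obs.append(
            OBResponse(
                responses=responses,
                positions=positions,
                ob_id=meta["ob_id"],
                mouse_id=meta["mouse_id"],
                baseline_f=baseline,
            )
        )
    if not obs:
        raise FileNotFoundError(f"no *.responses.tsv files under {indir}")
    return ResponseDataset(obs)
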