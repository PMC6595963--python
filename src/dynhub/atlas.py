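"""AAL 90-region parcellation metadata.

The cerebrum is divided into 90 regions (cerebellum excluded) following the
Automated Anatomical Labeling atlas.  Every topographic summary in this
package is table-driven: each region carries an anterior / posterior /
subcortical class and a default-mode-network (DMN) membership flag.

The anterior class covers the frontal lobe, the central/sensorimotor strip,
the parietal lobe (including precuneus, supramarginal and angular gyri and
the paracentral lobule), the insula and the anterior and middle cingulate.
The posterior class covers the occipital and temporal lobes, the posterior
cingulate and the fusiform/lingual/cuneus/calcarine cortex.  The subcortical
class is the hippocampus, parahippocampal gyrus, amygdala, caudate, putamen,
pallidum and thalamus.  DMN membership is a reconstructed, versioned table
(see ``data/aal90_atlas.tsv``); both classifications can be overridden by
supplying a custom atlas file with the same columns.

Region identity is always the AAL index (1..90); names are metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

N_REGIONS = 90
TOPO_CLASSES = ("anterior", "posterior", "subcortical")
_COLUMNS = ("index", "name", "abbreviation", "hemisphere", "topo_class", "dmn")


class AtlasError(ValueError):
    """Raised when an atlas table fails validation."""


@dataclass(frozen=True)
class Region:
    """One parcellation unit of the 90-region atlas."""

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    topo_class: str
    dmn: bool


class RegionTable:
    """Validated, ordered collection of the 90 atlas regions.

    Supports lookup by AAL index, by abbreviation, and by a loose
    "<hemisphere> <name>" query string (e.g. ``"right gyrus rectus"``).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise AtlasError(f"atlas table is missing columns {missing}")
        if len(frame) != N_REGIONS:
            raise AtlasError(
                f"atlas table must have {N_REGIONS} rows, found {len(frame)}"
            )
        frame["index"] = frame["index"].astype(int)
        dup = frame["index"][frame["index"].duplicated()]
        if len(dup):
            raise AtlasError(f"duplicate region index {dup.iloc[0]}")
        if sorted(frame["index"]) != list(range(1, N_REGIONS + 1)):
            missing_idx = sorted(set(range(1, N_REGIONS + 1)) - set(frame["index"]))
            raise AtlasError(f"region indices missing: {missing_idx}")
        bad = frame.loc[~frame["topo_class"].isin(TOPO_CLASSES)]
        if len(bad):
            row = bad.iloc[0]
            raise AtlasError(
                f"unknown topo_class {row['topo_class']!r} for region "
                f"{row['index']} ({row['abbreviation']})"
            )
        bad_hemi = frame.loc[~frame["hemisphere"].isin(("left", "right"))]
        if len(bad_hemi):
            row = bad_hemi.iloc[0]
            raise AtlasError(
                f"unknown hemisphere {row['hemisphere']!r} for region {row['index']}"
            )
        frame["dmn"] = frame["dmn"].astype(int).astype(bool)
        frame = frame.sort_values("index").reset_index(drop=True)
        self._frame = frame
        self._by_abbrev = {a: i for i, a in zip(frame["index"], frame["abbreviation"])}

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def abbreviations(self) -> list[str]:
        return list(self._frame["abbreviation"])

    @property
    def topo_class(self) -> np.ndarray:
        """Array of length 90 with the class of region i at position i-1."""
        return self._frame["topo_class"].to_numpy()

    @property
    def dmn_mask(self) -> np.ndarray:
        """Boolean array of length 90, True where region i-1 is in the DMN."""
        return self._frame["dmn"].to_numpy()

    def region(self, index: int) -> Region:
        if not 1 <= int(index) <= N_REGIONS:
            raise AtlasError(f"region index {index} outside 1..{N_REGIONS}")
        row = self._frame.iloc[int(index) - 1]
        return Region(
            index=int(row["index"]),
            name=row["name"],
            abbreviation=row["abbreviation"],
            hemisphere=row["hemisphere"],
            topo_class=row["topo_class"],
            dmn=bool(row["dmn"]),
        )

    def by_abbreviation(self, abbreviation: str) -> Region:
        try:
            return self.region(self._by_abbrev[abbreviation])
        except KeyError:
            raise AtlasError(f"unknown abbreviation {abbreviation!r}") from None

    def by_name(self, query: str) -> Region:
        """Look up a region by a loose name like ``"left precuneus"``.

        A leading "left"/"right" selects the hemisphere; the remainder must
        match one region name (case-insensitive substring match).
        """
        q = query.strip().lower()
        hemi = None
        for side in ("left", "right"):
            if q.startswith(side + " "):
                hemi = side
                q = q[len(side) + 1 :].strip()
        cand = self._frame
        if hemi is not None:
            cand = cand[cand["hemisphere"] == hemi]
        hit = cand[cand["name"].str.lower().str.contains(q, regex=False)]
        if len(hit) == 0:
            raise AtlasError(f"no region matches {query!r}")
        if len(hit) > 1:
            exact = hit[hit["name"].str.lower() == q]
            if len(exact) == 1:
                hit = exact
            else:
                names = list(hit["abbreviation"])
                raise AtlasError(f"ambiguous query {query!r}: matches {names}")
        return self.region(int(hit.iloc[0]["index"]))

    def __len__(self) -> int:
        return N_REGIONS

    def __iter__(self) -> Iterable[Region]:
        return (self.region(i) for i in range(1, N_REGIONS + 1))


def load_region_table(path: str = "packaged") -> RegionTable:
    """Load and validate an atlas TSV; ``"packaged"`` loads the shipped table."""
    if path == "packaged":
        with resources.files("dynhub.data").joinpath("aal90_atlas.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return RegionTable(frame)


def classify_selection(
    selected: Iterable[int], table: RegionTable
) -> Mapping[str, int]:
    """Count a set of selected regions by topographic class and DMN membership.

    Returns a dict with keys ``n_selected``, ``anterior``, ``posterior``,
    ``subcortical``, ``dmn`` and ``non_dmn``.  Class counts sum to
    ``n_selected``, as do the DMN counts.
    """
    sel = sorted({int(i) for i in selected})
    for i in sel:
        if not 1 <= i <= N_REGIONS:
            raise AtlasError(f"selected region index {i} outside 1..{N_REGIONS}")
    counts = {"n_selected": len(sel), "anterior": 0, "posterior": 0,
              "subcortical": 0, "dmn": 0, "non_dmn": 0}
    for i in sel:
        r = table.region(i)
        counts[r.topo_class] += 1
        counts["dmn" if r.dmn else "non_dmn"] += 1
    return counts
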