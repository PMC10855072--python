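"""Antibody panel handling.

A panel is a :class:`pandas.DataFrame` with columns ``target`` (marker name),
``metal`` (isotope tag) and ``role`` (pipe-joined subset of ``dna``,
``segmentation``, ``clustering``; empty string for markers used in neither).
Per-channel low-intensity thresholds are kept separate (see
:func:`imcpipe.preprocess.build_stack`) because they are a manually tuned
configuration, not a property of the antibody.
"""

from __future__ import annotations

import pandas as pd

DNA_CHANNEL = "DNA"

#: 28 metal-tagged markers of the mouse PDAC tumor-microenvironment panel,
#: in acquisition order.
PANEL_MARKERS: list[tuple[str, str]] = [
    ("Ly6G", "141Pr"),
    ("Vimentin", "143Nd"),
    ("MHC-II", "145Nd"),
    ("CD45", "147Sm"),
    ("PanCK", "148Nd"),
    ("Fibrinogen", "149Sm"),
    ("aSMA", "151Eu"),
    ("CK19", "152Sm"),
    ("F4/80", "153Eu"),
    ("PDGFRa", "154Sm"),
    ("uPAR", "155Gd"),
    ("PDGFRb", "156Gd"),
    ("E-cadherin", "158Gd"),
    ("CD3", "159Tb"),
    ("PV1", "160Gd"),
    ("CD4", "161Dy"),
    ("CD8", "163Dy"),
    ("Lyve-1", "164Dy"),
    ("Desmin", "165Ho"),
    ("CD31", "166Er"),
    ("Collagen IV", "167Er"),
    ("CD206", "168Er"),
    ("Collagen I", "169Tm"),
    ("CD44", "171Yb"),
    ("CD11b", "172Yb"),
    ("ZO-1", "173Yb"),
    ("CD103", "175Lu"),
    ("B220", "176Yb"),
]

#: The 19 markers used for UMAP reduction and clustering in the orthotopic
#: (Panc02) model.
ORTHOTOPIC_CLUSTERING_MARKERS: list[str] = [
    "Ly6G", "Vimentin", "CD45", "aSMA", "F4/80", "PDGFRa", "PDGFRb",
    "CD3", "CD4", "CD8", "Lyve-1", "Desmin", "CD31", "Collagen IV",
    "Collagen I", "CD11b", "ZO-1", "CD103", "B220",
]

#: The 21 markers used for clustering in the genetic KPC model.
KPC_CLUSTERING_MARKERS: list[str] = [
    "Ly6G", "Vimentin", "CD45", "PanCK", "aSMA", "CK19", "F4/80",
    "PDGFRa", "PDGFRb", "E-cadherin", "CD3", "CD4", "CD8", "Lyve-1",
    "Desmin", "CD31", "Collagen IV", "Collagen I", "ZO-1", "CD103", "B220",
]

#: Membrane / cytoplasm markers used (with DNA) for pixel classification.
DEFAULT_SEGMENTATION_MARKERS: list[str] = ["CD45", "aSMA", "ZO-1"]


def default_panel(clustering_markers: list[str] | None = None) -> pd.DataFrame:
    """Full 28-marker panel plus the iridium DNA channel (29 rows).

    Parameters
    ----------
    clustering_markers
        Markers flagged for clustering; defaults to the 19 orthotopic ones.
    """
    clustering = set(
        ORTHOTOPIC_CLUSTERING_MARKERS if clustering_markers is None else clustering_markers
    )
    rows = []
    for target, metal in PANEL_MARKERS:
        roles = []
        if target in DEFAULT_SEGMENTATION_MARKERS:
            roles.append("segmentation")
        if target in clustering:
            roles.append("clustering")
        rows.append({"target": target, "metal": metal, "role": "|".join(roles)})
    rows.append({"target": DNA_CHANNEL, "metal": "191Ir", "role": "dna|segmentation"})
    return pd.DataFrame(rows, columns=["target", "metal", "role"])


def make_panel(markers: list[str],
               segmentation: list[str] | None = None,
               clustering: list[str] | None = None) -> pd.DataFrame:
    """Build an ad-hoc panel (e.g. for a reduced synthetic marker set).

    ``markers`` must not include the DNA channel; it is appended with role
    ``dna|segmentation``. Metal tags are synthesized where unknown.
    """
    known = dict(PANEL_MARKERS)
    seg = set(segmentation or [])
    clu = set(clustering or [])
    missing = (seg | clu) - set(markers)
    if missing:
        raise KeyError(f"role markers not in panel: {sorted(missing)}")
    rows = []
    for i, m in enumerate(markers):
        roles = []
        if m in seg:
            roles.append("segmentation")
        if m in clu:
            roles.append("clustering")
        rows.append({"target": m, "metal": known.get(m, f"M{i:03d}"),
                     "role": "|".join(roles)})
    rows.append({"target": DNA_CHANNEL, "metal": "191Ir", "role": "dna|segmentation"})
    return pd.DataFrame(rows, columns=["target", "metal", "role"])


def validate_panel(panel: pd.DataFrame) -> None:
    for col in ("target", "metal", "role"):
        if col not in panel.columns:
            raise ValueError(f"panel missing column {col!r}")
    if panel["target"].duplicated().any():
        raise ValueError("duplicate marker names in panel")
    if panel["metal"].duplicated().any():
        raise ValueError("duplicate metal tags in panel")


def role_markers(panel: pd.DataFrame, role: str) -> list[str]:
    """Markers flagged with ``role``, in panel order."""
    sel = panel["role"].fillna("").str.split("|").apply(lambda r: role in r)
    return panel.loc[sel, "target"].tolist()


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, keep_default_na=False)
    validate_panel(panel)
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel[["target", "metal", "role"]].to_csv(path, index=False)
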