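"""Built-in fold descriptions used as fixtures throughout the package.

``tp3_t6`` is the (3+1) hybrid three-layer fold of the 23-nt PARP1-promoter
sequence variant TP3-T6 (an A10 bulge on the antiparallel tract and a
G2-G14-T20 triple capping the top tetrad).  The other entries are idealised
reference architectures: an all-parallel three-layer fold and a
thrombin-aptamer-like 2+2 antiparallel two-layer fold.
"""
from __future__ import annotations

from .topology import QuadruplexTopology, build_topology


def tp3_t6_spec() -> dict:
    return {
        "sequence_id": "TP3-T6",
        "residues": "TGGGGTCCGAGGCGGGGCTTGGG",
        "tetrads": [(3, 21, 15, 12), (4, 11, 16, 22), (5, 9, 17, 23)],
        "syn": [3, 9, 11, 15, 21],
        # G14 caps the top tetrad via a reverse-Hoogsteen pair with G2; its
        # glycosidic state is not spectroscopically fixed and defaults to anti
        "anti": [14],
        "bulges": [10],
        "capping": [
            {
                "mode": "reverse_hoogsteen",
                "partners": (14, 2),
                "bonds": [
                    ((14, "H21"), (2, "O6")),
                    ((14, "H1"), (2, "N7")),
                    ((14, "N2"), (2, "O6")),
                    ((14, "N1"), (2, "N7")),
                ],
                "planar": True,
            },
            {
                "mode": "ambiguous",
                "partners": (2, 20),
                "bonds": [((2, "H1"), (20, "O2"))],
                "alternatives": [(20, "O2"), (20, "O4"), (20, "O4'")],
            },
        ],
    }


def tp3_spec() -> dict:
    """The wild-type TP3 fold (same core; G6 instead of T6)."""
    spec = tp3_t6_spec()
    spec["sequence_id"] = "TP3"
    spec["residues"] = "TGGGGGCCGAGGCGGGGCTTGGG"
    return spec


def parallel_3layer_spec() -> dict:
    """All-parallel three-layer fold of a canonical pG4, propeller loops only."""
    return {
        "sequence_id": "par3",
        "residues": "TGGGTTAGGGTTAGGGTTAGGG",
        "tetrads": [(2, 8, 14, 20), (3, 9, 15, 21), (4, 10, 16, 22)],
        "syn": [],
    }


def antiparallel_2p2_spec() -> dict:
    """Two-layer 2+2 antiparallel (chair-like) fold, alternating syn/anti."""
    return {
        "sequence_id": "anti22",
        "residues": "GGTTGGTGTGGTTGG",
        # the lower layer's hydrogen-bond cycle runs opposite to the upper one
        "tetrads": [(1, 6, 10, 15), (2, 14, 11, 5)],
        "syn": [1, 5, 10, 14],
    }


def tp3_t6_t14a2_spec() -> dict:
    """TP3-T6 with the capping pair swapped to a Hoogsteen T14.A2."""
    spec = tp3_t6_spec()
    spec["sequence_id"] = "TP3-T6-T14A2"
    s = list(spec["residues"])
    s[1], s[13] = "A", "T"
    spec["residues"] = "".join(s)
    spec["anti"] = []
    spec["capping"] = [
        {
            "mode": "hoogsteen",
            "partners": (14, 2),
            "bonds": [
                ((14, "H3"), (2, "N7")),
                ((2, "H62"), (14, "O4")),
            ],
            "planar": True,
        }
    ]
    return spec


FOLD_SPECS = {
    "tp3_t6_t14a2": tp3_t6_t14a2_spec,
    "tp3_t6": tp3_t6_spec,
    "tp3": tp3_spec,
    "parallel_3layer": parallel_3layer_spec,
    "antiparallel_2+2": antiparallel_2p2_spec,
}


def get_fold(name: str) -> QuadruplexTopology:
    try:
        spec = FOLD_SPECS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fold {name!r}; available: {sorted(FOLD_SPECS)}"
        ) from None
    return build_topology(spec)
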