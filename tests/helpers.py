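"""Builders for synthetic pair/transformation objects used in stats tests."""

from __future__ import annotations

from mmpamp.chem import EndpointData, EndpointValue
from mmpamp.fragment import FragmentKey
from mmpamp.index import MatchedPair, PairEndpointData, Transformation

SCAFFOLD = FragmentKey("c1ccc([*:1])cc1", 1, 6)
LEFT = FragmentKey("A[*:1]", 1, 1)
RIGHT = FragmentKey("B[*:1]", 1, 1)


def endpoint_value(value, kind="continuous", source="experimental", uncertainty=0.0,
                   in_domain=True):
    return EndpointValue(
        kind=kind, value=value, source=source,
        uncertainty=uncertainty if source == "predicted" else 0.0,
        in_domain=in_domain if source == "predicted" else True,
    )


def make_pair(i, value_a, value_b, endpoint="y", kind="continuous",
              source="experimental", uncertainty=0.0, in_domain=True,
              left=LEFT, right=RIGHT, scaffold=SCAFFOLD, prefix=""):
    data = PairEndpointData(
        a=EndpointData(
            **{
                "experimental" if source == "experimental" else "predicted": endpoint_value(
                    value_a, kind, source, uncertainty, in_domain
                )
            }
        ),
        b=EndpointData(
            **{
                "experimental" if source == "experimental" else "predicted": endpoint_value(
                    value_b, kind, source, uncertainty, in_domain
                )
            }
        ),
    )
    mol_a, mol_b = f"{prefix}a{i}", f"{prefix}b{i}"
    return MatchedPair(
        mol_a=mol_a, mol_b=mol_b, scaffold=scaffold, frag_a=left, frag_b=right,
        n_cuts=1, similarity=1.0, pair_group=(mol_a, mol_b), deltas={endpoint: data},
    )


def make_transformation(pairs, left=LEFT, right=RIGHT, n_cuts=1):
    return Transformation(
        id=f"{left.notation}>>{right.notation}",
        left=left, right=right, n_cuts=n_cuts,
        pairs=[(p, 1) for p in pairs],
    )
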