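import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bhlhkit.family_filter import ConservedPositionSet
from bhlhkit.profile_search import AlignedDomain
from bhlhkit.synthetic import DOMAIN_LENGTH, consensus_template


@pytest.fixture(scope="session")
def consensus() -> ConservedPositionSet:
    return ConservedPositionSet.default()


@pytest.fixture(scope="session")
def template_domain(consensus) -> str:
    """A gap-free domain matching every conserved position (seed 0)."""
    return consensus_template(consensus, seed=0, domain_len=DOMAIN_LENGTH)


def domain_with(template: str, **column_residues) -> AlignedDomain:
    """AlignedDomain from the template with columns overridden.

    Keyword arguments are c<column>=<residue>, e.g. c13="Q"; residue
    "-" places a gap.
    """
    residues = list(template)
    for key, res in column_residues.items():
        col = int(key.lstrip("c"))
        residues[col - 1] = res
    return AlignedDomain.from_sequence("".join(residues))
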