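"""Redundancy reduction among proteins identified by identical evidence.

A multi-species protein database yields orthologs matched by exactly the
same set of spectra.  Proteins whose spectrum-id sets are identical form a
group; from each group, either all members of the preferred species are
retained (to keep isoforms) or, when no preferred-species member exists,
one representative chosen by a deterministic tie-break.  Spectra-set
equality is exact set equality — a strict subset is *not* grouped
(parsimony inference is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .identifications import ProteinIdentification

PREFERRED_SPECIES = "Gossypium hirsutum"


@dataclass
class ProteinGroup:
    group_id: int
    representative: str
    members: list[str]            # accessions sharing one identical spectra set
    retained: list[str]           # subset of members kept in the reported list
    n_spectra: int


def group_proteins(
    proteins: list[ProteinIdentification],
    preferred_species: str = PREFERRED_SPECIES,
) -> list[ProteinGroup]:
    """Bucket proteins by their exact spectra set and apply retention rules.

    Output is invariant under permutation of the input: members are sorted
    by accession, groups by representative accession.  The representative
    is the lexicographically smallest retained accession.
    """
    buckets: dict[frozenset, list[ProteinIdentification]] = {}
    for prot in proteins:
        buckets.setdefault(frozenset(prot.spectra), []).append(prot)

    groups: list[ProteinGroup] = []
    for spectra, members in buckets.items():
        members = sorted(members, key=lambda p: p.accession)
        preferred = [p for p in members if p.species == preferred_species]
        if preferred:
            retained = [p.accession for p in preferred]
        else:
            retained = [members[0].accession]
        groups.append(
            ProteinGroup(
                group_id=0,
                representative=retained[0],
                members=[p.accession for p in members],
                retained=retained,
                n_spectra=len(spectra),
            )
        )
    groups.sort(key=lambda g: g.representative)
    for i, g in enumerate(groups, start=1):
        g.group_id = i
    return groups


def retained_protein_list(
    groups: list[ProteinGroup],
    proteins: list[ProteinIdentification] | None = None,
) -> list:
    """Concatenate retained members across groups, in stable group order.

    With ``proteins`` given, returns the ProteinIdentification objects;
    otherwise the retained accession strings.
    """
    accs = [acc for g in groups for acc in g.retained]
    if proteins is None:
        return accs
    by_acc = {p.accession: p for p in proteins}
    return [by_acc[a] for a in accs]


def write_group_report(groups: list[ProteinGroup], path) -> None:
    df = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "representative": [g.representative for g in groups],
            "retained": [";".join(g.retained) for g in groups],
            "members": [";".join(g.members) for g in groups],
            "n_spectra": [g.n_spectra for g in groups],
        }
    )
    df.to_csv(path, sep="\t", index=False)
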