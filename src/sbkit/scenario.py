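"""Classify the species-tree / supergene-tree pair into competing histories.

Given rooted trees over the same samples and a (species, variant) label for
every sample, the classifier applies explicit monophyly / sister-group
tests, in order:

1. *independent origins* -- each Sb-bearing species' Sb samples form a
   clade sister to that species' own SB samples;
2. *trans-species polymorphism* -- all Sb samples form one clade, species
   are monophyletic within it, and its sister group contains SB samples of
   every Sb-bearing species;
3. *introgression* -- all Sb samples form one clade whose sister group
   consists exclusively of SB samples of a proper subset of species (the
   donor lineage; possibly several labels when the donor clade spans
   paraphyletic nominal species, as with S. invicta/macdonaghi), with at
   least one non-donor sample inside the Sb clade;
4. otherwise *unresolved*.

On a polytomous tree, monophyly of a group means the smallest clade
containing it holds no foreign tip.  Ambiguity falls through to
*unresolved* rather than guessing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import dendropy

log = logging.getLogger(__name__)

SB = "SB"
Sb = "Sb"


@dataclass
class ScenarioCall:
    scenario: str  # trans_species | independent_origins | introgression | unresolved
    donor: tuple | None  # species labels of the donor lineage (introgression only)
    evidence: dict = field(default_factory=dict)
    introgression_subclades: list = field(default_factory=list)  # tip-label sets

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "donor": list(self.donor) if self.donor else None,
                "evidence": self.evidence,
                "introgression_subclades": [sorted(s) for s in self.introgression_subclades],
            },
            indent=1,
            sort_keys=True,
        )


def _tips(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _mrca(tree, labels):
    taxa = [tree.taxon_namespace.get_taxon(l) for l in labels]
    if len(labels) == 1:
        return tree.find_node_with_taxon_label(next(iter(labels)))
    return tree.mrca(taxa=taxa)


def _smallest_clade(tree, labels):
    node = _mrca(tree, labels)
    return node, _tips(node)


def _is_clade(tree, labels) -> bool:
    _, tips = _smallest_clade(tree, labels)
    return tips == frozenset(labels)


def _sister_tips(node, tree):
    parent = node.parent_node
    if parent is None:
        return None
    out = frozenset()
    for ch in parent.child_nodes():
        if ch is not node:
            out |= _tips(ch)
    return out


def _check_labels(tree, labels):
    for lf in tree.leaf_node_iter():
        if lf.taxon.label not in labels:
            raise ValueError(f"unlabeled tip {lf.taxon.label!r}")


def classify_scenario(
    species_tree: dendropy.Tree,
    supergene_tree: dendropy.Tree,
    labels: dict,
) -> ScenarioCall:
    """Apply the rule cascade to a rooted supergene tree.

    ``labels`` maps every sample name to a (species, variant) pair; the
    species tree is carried as context (both trees must be rooted to the
    same outgroup) but the discriminating structure lives in the supergene
    tree.
    """
    for t in (species_tree, supergene_tree):
        _check_labels(t, labels)
        t.is_rooted = True
    tree = supergene_tree
    sb_samples = frozenset(s for s, (sp, v) in labels.items() if v == Sb)
    sb_in_tree = sb_samples & _tips(tree.seed_node)
    if not sb_in_tree:
        raise ValueError("no Sb samples in the supergene tree")
    sb_species = sorted({labels[s][0] for s in sb_in_tree})
    if len(sb_species) < 2:
        raise ValueError("need Sb samples from at least 2 species")

    def group(species, variant):
        return frozenset(
            s
            for s, (sp, v) in labels.items()
            if sp == species and v == variant and s in _tips(tree.seed_node)
        )

    evidence: dict = {}

    # rule (i): independent origins
    per_species_own_sister = {}
    for sp in sb_species:
        own_sb = group(sp, Sb)
        own_SB = group(sp, SB)
        ok = False
        if own_sb and _is_clade(tree, own_sb):
            node, _ = _smallest_clade(tree, own_sb)
            sister = _sister_tips(node, tree)
            ok = bool(sister) and sister <= own_SB
        per_species_own_sister[sp] = ok
    evidence["per_species_sb_sister_to_own_SB"] = per_species_own_sister
    if all(per_species_own_sister.values()):
        return ScenarioCall("independent_origins", None, evidence)

    # shared structure for rules (ii) and (iii)
    sb_mono = _is_clade(tree, sb_in_tree)
    evidence["sb_monophyletic"] = sb_mono
    if sb_mono:
        sb_node, _ = _smallest_clade(tree, sb_in_tree)
        sister = _sister_tips(sb_node, tree) or frozenset()
        sister_variants = {labels[s][1] for s in sister}
        sister_species = sorted({labels[s][0] for s in sister})
        evidence["sb_sister_species"] = sister_species
        evidence["sb_sister_SB_only"] = sister_variants == {SB}

        # rule (ii): trans-species polymorphism
        species_mono_within = all(
            _is_clade(tree, group(sp, Sb)) for sp in sb_species
        )
        evidence["species_monophyletic_within_sb_clade"] = species_mono_within
        sister_has_all = all(
            any(labels[s][0] == sp and labels[s][1] == SB for s in sister)
            for sp in sb_species
        )
        evidence["sister_contains_SB_of_all_sb_species"] = sister_has_all
        if species_mono_within and sister_has_all:
            return ScenarioCall("trans_species", None, evidence)

        # rule (iii): introgression
        if evidence["sb_sister_SB_only"] and sister_species:
            donor = tuple(sister_species)
            non_donor_inside = [
                s for s in _tips(sb_node) if labels[s][0] not in donor
            ]
            evidence["sb_sister_to_donor_SB"] = True
            evidence["non_donor_samples_inside_sb_clade"] = len(non_donor_inside)
            if non_donor_inside:
                count, subclades = count_introgression_clades(tree, donor, labels)
                return ScenarioCall("introgression", donor, evidence, subclades)

    return ScenarioCall("unresolved", None, evidence)


def count_introgression_clades(supergene_tree: dendropy.Tree, donor, labels):
    """Maximal clades of non-donor Sb samples inside the Sb clade.

    Returns (count, [tip-label sets]).  The count is a lower bound on the
    number of independent introgression events: adjacent recipient
    subclades may reflect secondary transfer between recipients.
    """
    if isinstance(donor, str):
        donor = (donor,)
    donor = tuple(donor)
    supergene_tree.is_rooted = True
    tree_tips = _tips(supergene_tree.seed_node)
    known_species = {sp for sp, v in labels.values()}
    for d in donor:
        if d not in known_species:
            raise ValueError(f"donor species {d!r} not in the label map")
    sb_in_tree = frozenset(
        s for s in tree_tips if labels[s][1] == Sb
    )
    sb_node, _ = _smallest_clade(supergene_tree, sb_in_tree)

    def non_donor_sb(tipset):
        return all(labels[s][0] not in donor and labels[s][1] == Sb for s in tipset)

    subclades = []

    def walk(node):
        tips = _tips(node)
        if non_donor_sb(tips):
            subclades.append(tips)
            return
        for ch in node.child_nodes():
            walk(ch)

    walk(sb_node)
    for i, sc in enumerate(subclades):
        sp = sorted({labels[s][0] for s in sc})
        log.info("introgression subclade %d: %s (%s)", i + 1, sorted(sc), sp)
    return len(subclades), subclades
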