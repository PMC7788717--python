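"""Structural model container: stoichiometry, categories, GPRs, balances."""

import itertools
import random

import numpy as np
import pytest

from oleaflux.elements import FormulaError, molecular_weight, parse_formula
from oleaflux.model import (
    GprExpression,
    MetabolicModel,
    Metabolite,
    Reaction,
    classify_reactions,
    evaluate_gpr,
    gpr_from_string,
    mass_balance_report,
    stoichiometric_matrix,
    StructuralIntegrityError,
)


def small_model():
    m = MetabolicModel("m", compartments={"c": "cytosol", "e": "extracellular"})
    m.add_metabolite(Metabolite("a_c", compartment="c", formula="C6H12O6"))
    m.add_metabolite(Metabolite("b_c", compartment="c", formula="C6H12O6"))
    m.add_metabolite(Metabolite("a_e", compartment="e", formula="C6H12O6"))
    return m


class TestStoichiometricMatrix:
    def test_single_reaction_signs(self):
        m = small_model()
        m.add_reaction(Reaction(id="R1", stoichiometry={"a_c": -1, "b_c": 1}))
        S, mets, rxns = stoichiometric_matrix(m)
        assert rxns == ["R1"]
        assert S[mets.index("a_c"), 0] == -1
        assert S[mets.index("b_c"), 0] == 1

    def test_empty_model_gives_empty_matrix(self):
        m = MetabolicModel("empty", compartments={"c": "c"})
        S, mets, rxns = stoichiometric_matrix(m)
        assert S.shape == (0, 0) and mets == [] and rxns == []

    def test_round_trip_reproduces_stoichiometry(self, toy_model):
        S, mets, rxns = stoichiometric_matrix(toy_model)
        for j, rid in enumerate(rxns):
            rebuilt = {
                mets[i]: S[i, j] for i in range(len(mets)) if S[i, j] != 0
            }
            assert rebuilt == toy_model.reactions[rid].stoichiometry

    def test_undeclared_metabolite_rejected(self):
        m = small_model()
        with pytest.raises(StructuralIntegrityError):
            m.add_reaction(Reaction(id="bad", stoichiometry={"ghost": -1}))


class TestClassification:
    def test_one_of_each_category(self):
        m = small_model()
        m.add_reaction(Reaction(id="EX_a", stoichiometry={"a_e": -1}))
        m.add_reaction(Reaction(id="T_a", stoichiometry={"a_e": -1, "a_c": 1}))
        m.add_reaction(Reaction(id="R1", stoichiometry={"a_c": -1, "b_c": 1}))
        counts = classify_reactions(m)
        assert counts == {"exchange": 1, "transport": 1, "metabolic": 1}

    def test_counts_partition_reaction_set(self, toy_model):
        counts = classify_reactions(toy_model)
        assert sum(counts.values()) == len(toy_model.reactions)

    def test_toy_counts_match_manifest(self, toy_model, toy_manifest):
        assert dict(classify_reactions(toy_model)) == toy_manifest.category_counts


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "formula,expected_g_mol",
        [("C3H8O3", 92.09), ("H", 1.008), ("C6H12O6", 180.16), ("H2O", 18.02)],
    )
    def test_known_compounds(self, formula, expected_g_mol):
        assert molecular_weight(formula) * 1000 == pytest.approx(expected_g_mol, abs=0.01)

    def test_additive_under_concatenation(self):
        rng = random.Random(0)
        pool = ["C6H12O6", "H2O", "C3H8O3", "NH4Cl", "C10H12N5O13P3"]
        for _ in range(20):
            f1, f2 = rng.choice(pool), rng.choice(pool)
            assert molecular_weight(f1 + f2) == pytest.approx(
                molecular_weight(f1) + molecular_weight(f2), rel=1e-12
            )

    def test_unknown_element_raises(self):
        with pytest.raises(FormulaError):
            molecular_weight("C6Qq2")

    def test_parse_counts(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}


def _brute_force(expr, deleted):
    if expr.op == "gene":
        return expr.gene not in deleted
    values = [_brute_force(c, deleted) for c in expr.children]
    return all(values) if expr.op == "and" else any(values)


def _random_tree(rng, genes):
    if len(genes) == 1:
        return GprExpression("gene", gene=genes[0])
    k = rng.randint(1, len(genes) - 1)
    left, right = genes[:k], genes[k:]
    op = rng.choice(["and", "or"])
    return GprExpression(op, children=(_random_tree(rng, left), _random_tree(rng, right)))


class TestGpr:
    def test_or_survives_single_deletion(self):
        assert evaluate_gpr(gpr_from_string("g1 or g2"), {"g1"}) is True

    def test_and_broken_by_single_deletion(self):
        assert evaluate_gpr(gpr_from_string("g1 and g2"), {"g1"}) is False

    def test_absent_gpr_unaffected(self):
        assert evaluate_gpr(None, {"g1"}) is True

    def test_random_trees_match_truth_table(self):
        rng = random.Random(7)
        for _ in range(30):
            n = rng.randint(1, 6)
            genes = [f"g{i}" for i in range(n)]
            tree = _random_tree(rng, genes)
            for r in range(n + 1):
                for deleted in itertools.combinations(genes, r):
                    assert tree.evaluate(set(deleted)) == _brute_force(tree, set(deleted))

    def test_parse_precedence_and_parens(self):
        tree = gpr_from_string("g1 and (g2 or g3)")
        assert tree.evaluate({"g2", "g3"}) is False
        assert tree.evaluate({"g2"}) is True
        tree2 = gpr_from_string("g1 or g2 and g3")  # and binds tighter
        assert tree2.evaluate({"g1"}) is True       # (g2 and g3) still active
        assert tree2.evaluate({"g1", "g2"}) is False


class TestMassBalance:
    def test_balanced_split(self):
        m = MetabolicModel("m", compartments={"c": "c"})
        m.add_metabolite(Metabolite("hex", compartment="c", formula="C6H12O6"))
        m.add_metabolite(Metabolite("tri", compartment="c", formula="C3H6O3"))
        m.add_reaction(Reaction(id="SPLIT", stoichiometry={"hex": -1, "tri": 2}))
        report = mass_balance_report(m)
        assert report.loc[report.reaction == "SPLIT", "status"].item() == "balanced"

    def test_carbon_imbalance_reported(self):
        m = MetabolicModel("m", compartments={"c": "c"})
        m.add_metabolite(Metabolite("hex", compartment="c", formula="C6H12O6"))
        m.add_metabolite(Metabolite("tri", compartment="c", formula="C3H6O3"))
        m.add_reaction(Reaction(id="LOSSY", stoichiometry={"hex": -1, "tri": 1}))
        row = mass_balance_report(m).set_index("reaction").loc["LOSSY"]
        assert row.status == "imbalanced"
        assert row.imbalance["C"] == pytest.approx(-3)

    def test_toy_clean_outside_manifest_lumps(self, toy_model, toy_manifest):
        report = mass_balance_report(toy_model)
        bad = set(report[report.status == "imbalanced"].reaction)
        assert bad == set()
        # every manifest-listed lumped reaction is exempt, not judged balanced
        exempt = set(report[report.status == "exempt"].reaction)
        lumps = set(toy_manifest.lumped_reactions)
        assert lumps <= exempt
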