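"""Universe mapping, carving, penalties and gap-filling."""

import itertools
import random

import pytest

from conftest import toy_metabolite
from panflux.fba import run_fba
from panflux.gpr import parse
from panflux.model import MediumRecipe, Model, Reaction, apply_medium
from panflux.reconstruction import (GeneSupportMap, SupportHit, Universe,
                                    carve_draft_pan, compute_penalties,
                                    gapfill_min_penalty, P_MAX, P_MIN)


def _support(mapping):
    sm = GeneSupportMap()
    for gene, clusters in mapping.items():
        for cl, (ident, cov) in clusters.items():
            sm.hits.setdefault(gene, {})[cl] = SupportHit(ident, cov)
    return sm


class TestSupportMap:
    def test_identical_representative_full_support(self, world,
                                                   recon_result):
        support = recon_result.support
        # the glyc family representative must support u_glyc strongly
        hits = support.hits.get("u_glyc", {})
        assert hits, "glyc family not mapped"
        assert max(h.identity for h in hits.values()) >= 0.95

    def test_unsupported_universal_gene_absent(self, recon_result):
        assert "u_unused" not in recon_result.support.hits

    def test_planted_family_homology_design(self, world, recon_result):
        """Each mapped universal gene is supported exactly by the
        cluster of its own planted family."""
        gene_family = {}
        for cl in recon_result.clusters:
            fams = {g.rsplit("_", 1)[-1] for g in cl.all_genes()
                    if not g.split("_", 1)[-1].startswith("rec")}
            if len(fams) == 1:
                gene_family[cl.id] = fams.pop()
        for ugene, hits in recon_result.support.hits.items():
            fam = ugene[2:]  # u_<family>
            best = max(hits, key=lambda c: hits[c].score)
            assert gene_family.get(best) == fam


def _toy_universe():
    m = Model("u")
    for mid in ("a_e", "a_c", "b_c"):
        m.add_metabolite(toy_metabolite(mid))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-1000, upper_bound=1000))
    m.add_reaction(Reaction("At", stoichiometry={"a_e": -1, "a_c": 1},
                            lower_bound=0, gpr=parse("u1 or u2")))
    m.add_reaction(Reaction("AB", stoichiometry={"a_c": -1, "b_c": 1},
                            lower_bound=0, gpr=parse("u3 and u4")))
    m.add_reaction(Reaction("SPONT", stoichiometry={"a_c": -1, "b_c": 1},
                            lower_bound=0, spontaneous=True))
    m.add_reaction(Reaction("BIO", stoichiometry={"b_c": -1}, lower_bound=0))
    m.objective = "BIO"
    seqs = {g: "MKLV" * 40 for g in ("u1", "u2", "u3", "u4")}
    return Universe(m, seqs)


class TestCarve:
    def test_partial_complex_excluded(self):
        u = _toy_universe()
        support = _support({"u3": {"C1": (1.0, 1.0)}})  # u4 unsupported
        draft = carve_draft_pan(u, support)
        assert "AB" not in draft.reactions

    def test_isoform_branch_survives(self):
        u = _toy_universe()
        support = _support({"u2": {"C7": (1.0, 1.0)}})
        draft = carve_draft_pan(u, support)
        assert str(draft.reactions["At"].gpr) == "C7"

    def test_saturated_support_reproduces_universe(self):
        u = _toy_universe()
        support = _support({g: {"C1": (1.0, 1.0)} for g in "u1 u2 u3 u4".split()})
        draft = carve_draft_pan(u, support)
        internal_u = {r for r, rxn in u.model.reactions.items()
                      if not u.model.is_boundary(rxn)}
        internal_d = {r for r, rxn in draft.reactions.items()
                      if not draft.is_boundary(rxn)}
        assert internal_d == internal_u

    def test_spontaneous_kept_without_support(self):
        draft = carve_draft_pan(_toy_universe(), _support({}))
        assert "SPONT" in draft.reactions
        assert draft.reactions["SPONT"].gpr.is_empty

    def test_exchanges_follow_retained_metabolites(self):
        u = _toy_universe()
        draft = carve_draft_pan(u, _support({"u1": {"C1": (1.0, 1.0)}}))
        assert "EX_a_e" in draft.reactions
        assert draft.reactions["EX_a_e"].lower_bound == 0.0

    def test_monotone_in_support(self):
        u = _toy_universe()
        weak = carve_draft_pan(u, _support({"u1": {"C1": (1.0, 1.0)}}))
        strong = carve_draft_pan(u, _support({
            "u1": {"C1": (1.0, 1.0)}, "u3": {"C2": (1.0, 1.0)},
            "u4": {"C3": (1.0, 1.0)}}))
        assert set(weak.reactions) <= set(strong.reactions)

    def test_universe_without_objective_rejected(self):
        u = _toy_universe()
        u.model.objective = None
        with pytest.raises(ValueError):
            carve_draft_pan(u, _support({}))


class TestPenalties:
    def test_fully_supported_gets_p_min(self):
        u = _toy_universe()
        support = _support({g: {"C1": (1.0, 1.0)} for g in "u1 u2 u3 u4".split()})
        pen = compute_penalties(u, support)
        assert pen["At"] == pytest.approx(P_MIN)
        assert pen["AB"] == pytest.approx(P_MIN)

    def test_zero_support_gets_p_max(self):
        pen = compute_penalties(_toy_universe(), _support({}))
        assert pen["AB"] == pytest.approx(P_MAX)

    def test_spontaneous_and_exchange_get_p_min(self):
        pen = compute_penalties(_toy_universe(), _support({}))
        assert pen["SPONT"] == pen["EX_a_e"] == pytest.approx(P_MIN)

    def test_complex_limited_by_weakest_subunit(self):
        u = _toy_universe()
        pen = compute_penalties(u, _support({
            "u3": {"C1": (1.0, 1.0)}, "u4": {"C2": (0.5, 1.0)}}))
        expected = P_MIN + (1 - 0.5) * (P_MAX - P_MIN)
        assert pen["AB"] == pytest.approx(expected)

    def test_monotone_in_scores(self):
        rng = random.Random(9)
        u = _toy_universe()
        for _ in range(50):
            scores = {g: rng.random() for g in "u1 u2 u3 u4".split()}
            sup = _support({g: {"C1": (s, 1.0)} for g, s in scores.items()})
            pen = compute_penalties(u, sup)
            bump = dict(scores)
            g = rng.choice(list(scores))
            bump[g] = min(1.0, scores[g] + rng.random() * (1 - scores[g]))
            sup2 = _support({g: {"C1": (s, 1.0)} for g, s in bump.items()})
            pen2 = compute_penalties(u, sup2)
            for rid in pen:
                assert pen2[rid] <= pen[rid] + 1e-12


def _gap_model(n_paths=2):
    """a_e -> a_c -> ... -> b_c -> biomass, with the a->b step missing
    from the model but present in the repository via several candidate
    paths of differing penalty."""
    m = Model("gappy")
    for mid in ("a_e", "a_c", "b_c"):
        m.add_metabolite(toy_metabolite(mid))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-10, upper_bound=1000))
    m.add_reaction(Reaction("At", stoichiometry={"a_e": -1, "a_c": 1},
                            lower_bound=0))
    m.add_reaction(Reaction("BIO", stoichiometry={"b_c": -1}, lower_bound=0))
    m.objective = "BIO"
    repo = m.copy()
    repo.add_metabolite(toy_metabolite("x_c"))
    repo.add_reaction(Reaction("DIRECT", stoichiometry={"a_c": -1, "b_c": 1},
                               lower_bound=0))
    repo.add_reaction(Reaction("STEP1", stoichiometry={"a_c": -1, "x_c": 1},
                               lower_bound=0))
    repo.add_reaction(Reaction("STEP2", stoichiometry={"x_c": -1, "b_c": 1},
                               lower_bound=0))
    return m, repo


MEDIUM = MediumRecipe("toy", {"a_e": 10.0})


class TestGapfill:
    def test_growing_model_needs_nothing(self):
        m, repo = _gap_model()
        m.add_reaction(Reaction("DIRECT", stoichiometry={"a_c": -1, "b_c": 1},
                                lower_bound=0))
        result, aug = gapfill_min_penalty(m, repo, MEDIUM, 0.1)
        assert result.status == "success" and result.added == []

    def test_picks_cheaper_two_step_path(self):
        m, repo = _gap_model()
        penalties = {"DIRECT": 1.0, "STEP1": 0.3, "STEP2": 0.3}
        result, aug = gapfill_min_penalty(m, repo, MEDIUM, 0.1, penalties)
        assert result.added == ["STEP1", "STEP2"]
        assert result.total_penalty == pytest.approx(0.6)

    def test_picks_direct_when_cheaper(self):
        m, repo = _gap_model()
        penalties = {"DIRECT": 0.5, "STEP1": 0.3, "STEP2": 0.3}
        result, _ = gapfill_min_penalty(m, repo, MEDIUM, 0.1, penalties)
        assert result.added == ["DIRECT"]

    def test_infeasible_reports_without_mutation(self):
        m, repo = _gap_model()
        repo.remove_reactions(["DIRECT", "STEP1", "STEP2"])
        result, aug = gapfill_min_penalty(m, repo, MEDIUM, 0.1)
        assert result.status == "infeasible"
        assert set(aug.reactions) == set(m.reactions)

    def test_achieved_flux_meets_minimum(self):
        m, repo = _gap_model()
        result, aug = gapfill_min_penalty(m, repo, MEDIUM, 0.1)
        assert result.achieved_flux >= 0.1
        check = run_fba(apply_medium(aug, MEDIUM))
        assert check.objective_value >= 0.1

    def test_rejects_nonpositive_min_flux(self):
        m, repo = _gap_model()
        with pytest.raises(ValueError):
            gapfill_min_penalty(m, repo, MEDIUM, 0.0)


def brute_force_gapfill(model, repo, medium, min_flux, penalties):
    """Oracle: enumerate every candidate subset, keep the cheapest that
    reaches min_flux."""
    candidates = sorted(r for r in repo.reactions if r not in model.reactions)
    best = None
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            cost = sum(penalties.get(r, 1.0) for r in subset)
            if best is not None and cost >= best - 1e-9:
                continue
            trial = model.copy()
            for rid in subset:
                for mid in repo.reactions[rid].stoichiometry:
                    if mid not in trial.metabolites:
                        trial.add_metabolite(repo.metabolites[mid].copy())
                trial.add_reaction(repo.reactions[rid].copy())
            res = run_fba(apply_medium(trial, medium, on_missing="warn"))
            if res.status == "optimal" and res.objective_value >= min_flux:
                best = cost
    return best


class TestGapfillOptimality:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_subset_enumeration(self, seed):
        """Random chain worlds with <= 12 candidate reactions: MILP
        total penalty equals the brute-force subset minimum."""
        rng = random.Random(seed)
        n = rng.randint(3, 6)
        m = Model("chainworld")
        mids = [f"m{i}_c" for i in range(n + 1)]
        for mid in ["s_e"] + mids:
            m.add_metabolite(toy_metabolite(mid))
        m.add_reaction(Reaction("EX_s_e", stoichiometry={"s_e": -1},
                                lower_bound=-10, upper_bound=1000))
        m.add_reaction(Reaction("UP", stoichiometry={"s_e": -1, "m0_c": 1},
                                lower_bound=0))
        m.add_reaction(Reaction("BIO", stoichiometry={mids[-1]: -1},
                                lower_bound=0))
        m.objective = "BIO"
        repo = m.copy()
        penalties = {}
        for i in range(n):  # two parallel candidate steps per link
            for tag in ("a", "b"):
                rid = f"L{i}{tag}"
                repo.add_reaction(Reaction(
                    rid, stoichiometry={mids[i]: -1, mids[i + 1]: 1},
                    lower_bound=0))
                penalties[rid] = round(rng.uniform(0.1, 2.0), 3)
        medium = MediumRecipe("s", {"s_e": 10.0})
        result, aug = gapfill_min_penalty(m, repo, medium, 0.05, penalties)
        oracle = brute_force_gapfill(m, repo, medium, 0.05, penalties)
        assert result.status == "success"
        assert result.total_penalty == pytest.approx(oracle)
        assert run_fba(apply_medium(aug, medium)).objective_value >= 0.05
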