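"""BRH orthologs, reference translation, expansion, orphan GPRs."""

import random

import pytest

from conftest import toy_metabolite
from panflux.align import align_identity
from panflux.expansion import (REF_ONLY_PREFIX, BrhParams, brh_map,
                               expand_with_draft, supplement_orphan_gprs,
                               translate_reference_gprs)
from panflux.gpr import EMPTY, parse
from panflux.model import Model, Reaction, count_orphans
from panflux.pangenome import PAM, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _mutant(rng, seq, n):
    out = list(seq)
    for p in rng.sample(range(len(seq)), n):
        out[p] = rng.choice([a for a in AA if a != out[p]])
    return "".join(out)


def brute_force_brh(strain_records, ref_proteome, params=BrhParams()):
    """Independent mutual-best oracle over all admissible pairs."""
    scored = {}
    for rec in strain_records:
        for rg, rseq in ref_proteome.items():
            st = align_identity(rec.sequence, rseq)
            if (st.identity >= params.id_min and st.coverage_a >= params.cov_min
                    and st.coverage_b >= params.cov_min):
                scored[(rec.gene, rg)] = st.score
    pairs = []
    for (g, rg), s in scored.items():
        best_g = min(((-v, r) for (q, r), v in scored.items() if q == g))[1]
        best_r = min(((-v, q) for (q, r), v in scored.items() if r == rg))[1]
        if best_g == rg and best_r == g:
            pairs.append((g, rg, s))
    return sorted(pairs)


class TestBrh:
    def test_identical_proteomes_give_identity_mapping(self):
        rng = random.Random(0)
        seqs = {f"f{i}": "".join(rng.choice(AA) for _ in range(120))
                for i in range(4)}
        records = {"s1": [ProteinRecord(f"s1_{f}", "s1", seq)
                          for f, seq in seqs.items()]}
        ref = {f"r_{f}": seq for f, seq in seqs.items()}
        out = brh_map(records, ref)
        assert {(g, r) for g, r, _ in out.pairs["s1"]} == \
            {(f"s1_{f}", f"r_{f}") for f in seqs}

    def test_non_mutual_best_rejected(self):
        rng = random.Random(1)
        base = "".join(rng.choice(AA) for _ in range(150))
        near = _mutant(rng, base, 2)     # ref gene closest to base
        far = _mutant(rng, base, 15)     # strain gene: best hit is near
        records = {"s1": [ProteinRecord("s1_far", "s1", far),
                          ProteinRecord("s1_base", "s1", base)]}
        ref = {"r_near": near}
        out = brh_map(records, ref)
        # r_near's best is s1_base, so (s1_far, r_near) must be rejected
        genes = {g for g, _, _ in out.pairs["s1"]}
        assert "s1_far" not in genes

    @pytest.mark.parametrize("seed", range(10))
    def test_random_toys_match_bruteforce_oracle(self, seed):
        rng = random.Random(seed)
        n_fam = 6
        bases = ["".join(rng.choice(AA) for _ in range(rng.randint(80, 160)))
                 for _ in range(n_fam)]
        records = [ProteinRecord(f"s1_g{i}", "s1",
                                 _mutant(rng, bases[i % n_fam], rng.randint(0, 6)))
                   for i in range(10)]
        ref = {f"r{i}": _mutant(rng, bases[i % n_fam], rng.randint(0, 6))
               for i in range(10)}
        out = brh_map({"s1": records}, ref)
        assert out.pairs["s1"] == brute_force_brh(records, ref)


def _reference_model():
    m = Model("ref")
    for mid in ("a_c", "b_c", "c_c"):
        m.add_metabolite(toy_metabolite(mid, "CH4", 0))
    m.add_reaction(Reaction("R1", stoichiometry={"a_c": -1, "b_c": 1},
                            gpr=parse("rg1")))
    m.add_reaction(Reaction("R2", stoichiometry={"b_c": -1, "c_c": 1},
                            gpr=parse("rg2 and rg3")))
    m.add_reaction(Reaction("BIO", stoichiometry={"c_c": -1},
                            lower_bound=0))
    m.objective = "BIO"
    return m


class TestTranslate:
    def _pam(self):
        pam = PAM(["C1", "C2", "C3"], ["s1", "s2"])
        for s in ("s1", "s2"):
            pam.add_gene("C1", s, f"{s}_a")
            pam.add_gene("C2", s, f"{s}_b")
        pam.add_gene("C3", "s1", "s1_c")
        return pam

    def _orthologs(self):
        from panflux.expansion import OrthologMap
        om = OrthologMap()
        om.pairs = {"s1": [("s1_a", "rg1", 1.0), ("s1_b", "rg2", 1.0)],
                    "s2": [("s2_a", "rg1", 1.0), ("s2_b", "rg2", 1.0)]}
        return om

    def test_majority_vote_assignment(self):
        translated, om = translate_reference_gprs(
            _reference_model(), self._orthologs(), self._pam())
        assert om.gene_to_cluster == {"rg1": "C1", "rg2": "C2"}
        assert str(translated.reactions["R1"].gpr) == "C1"

    def test_unmapped_gene_becomes_placeholder_and_reaction_stays(self):
        translated, om = translate_reference_gprs(
            _reference_model(), self._orthologs(), self._pam())
        assert "rg3" in om.unmapped
        assert "R2" in translated.reactions
        leaves = translated.reactions["R2"].gpr.genes()
        assert REF_ONLY_PREFIX + "rg3" in leaves

    def test_reactions_and_bounds_copied_verbatim(self):
        ref = _reference_model()
        translated, _ = translate_reference_gprs(ref, self._orthologs(),
                                                 self._pam())
        assert set(translated.reactions) == set(ref.reactions)
        for rid in ref.reactions:
            assert translated.reactions[rid].stoichiometry == \
                ref.reactions[rid].stoichiometry


def _draft_with(extra_balanced=True):
    m = Model("draft")
    for mid in ("a_c", "b_c", "c_c"):
        m.add_metabolite(toy_metabolite(mid, "CH4", 0))
    m.add_metabolite(toy_metabolite("d_c", "CH4", 0))
    m.add_reaction(Reaction("R1", stoichiometry={"a_c": -1, "b_c": 1},
                            gpr=parse("C1")))
    m.add_reaction(Reaction("R2", stoichiometry={"b_c": -1, "c_c": 1},
                            gpr=parse("C2")))
    m.add_reaction(Reaction("NEW1", stoichiometry={"c_c": -1, "d_c": 1},
                            gpr=parse("C3")))
    if not extra_balanced:
        m.add_reaction(Reaction("BAD", stoichiometry={"c_c": -1, "d_c": 2},
                                gpr=parse("C3")))
    m.objective = None
    return m


class TestExpand:
    def test_draft_subset_of_reference_is_noop(self):
        ref = _reference_model()
        draft = Model("draft")
        for mid in ("a_c", "b_c"):
            draft.add_metabolite(toy_metabolite(mid, "CH4", 0))
        draft.add_reaction(Reaction("R1", stoichiometry={"a_c": -1, "b_c": 1},
                                    gpr=parse("C1")))
        expanded, report = expand_with_draft(ref, draft)
        assert set(expanded.reactions) == set(ref.reactions)
        assert report.added_reactions == []

    def test_new_balanced_reaction_added(self):
        expanded, report = expand_with_draft(_reference_model(), _draft_with())
        assert "NEW1" in expanded.reactions
        assert report.added_reactions == ["NEW1"]
        assert report.added_metabolites == ["d_c"]

    def test_unbalanced_candidate_skipped_and_reported(self):
        expanded, report = expand_with_draft(_reference_model(),
                                             _draft_with(extra_balanced=False))
        assert "BAD" not in expanded.reactions
        assert report.skipped_unbalanced == ["BAD"]

    def test_override_whitelist_admits_unbalanced(self):
        from panflux.expansion import ExpansionOverrides
        expanded, _ = expand_with_draft(
            _reference_model(), _draft_with(extra_balanced=False),
            overrides=ExpansionOverrides(allow_reactions={"BAD"}))
        assert "BAD" in expanded.reactions

    def test_reference_bounds_and_objective_inherited(self):
        ref = _reference_model()
        expanded, report = expand_with_draft(ref, _draft_with())
        assert expanded.objective == "BIO"
        for rid in ref.reactions:
            assert (expanded.reactions[rid].lower_bound,
                    expanded.reactions[rid].upper_bound) == \
                (ref.reactions[rid].lower_bound,
                 ref.reactions[rid].upper_bound)

    def test_planted_xylose_path_added_from_draft(self, recon_result):
        """The alternative-sugar catabolic route missing from the
        curated reference enters the pan during expansion."""
        report = recon_result.expansion_report
        assert {"XYLt", "XYLI", "XYLCAT"} <= set(report.added_reactions)
        assert "XYLt" not in recon_result.pan.id  # sanity: it is a reaction
        assert "XYLt" in recon_result.pan.reactions


class TestSupplementOrphans:
    def test_orphan_gets_draft_gpr(self):
        ref = _reference_model()
        ref.reactions["R1"].gpr = EMPTY  # curated orphan
        out = supplement_orphan_gprs(ref, _draft_with())
        assert str(out.reactions["R1"].gpr) == "C1"

    def test_orphan_absent_from_draft_unchanged(self):
        ref = _reference_model()
        ref.reactions["BIO"].gpr = EMPTY
        out = supplement_orphan_gprs(ref, _draft_with())
        assert out.reactions["BIO"].gpr.is_empty

    def test_nonempty_gpr_never_overwritten(self):
        ref = _reference_model()
        out = supplement_orphan_gprs(ref, _draft_with())
        assert str(out.reactions["R1"].gpr) == "rg1"

    def test_orphan_count_never_increases(self, recon_result):
        from panflux.expansion import expand_with_draft
        # re-run the supplement on the expanded model and compare counts
        before = count_orphans(recon_result.pan)[0]
        again = supplement_orphan_gprs(recon_result.pan, recon_result.draft)
        assert count_orphans(again)[0] <= before

    def test_world_reference_orphan_closed_ngam_preserved(self,
                                                          recon_result,
                                                          world):
        pan = recon_result.pan
        report = recon_result.expansion_report
        assert report.supplemented_orphans == ["GLCt"]
        assert not pan.reactions["GLCt"].gpr.is_empty
        from panflux.synthetic import NGAM_BOUNDS
        assert (pan.reactions["ATPM"].lower_bound,
                pan.reactions["ATPM"].upper_bound) == NGAM_BOUNDS
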