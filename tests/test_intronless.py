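import numpy as np
import pytest
from Bio.Seq import Seq

from chemorep.assembly import GenomeAssembly
from chemorep.hits import BestHitRegion
from chemorep.intronless import (
    FamilyProfile,
    GeneCall,
    V1R_PROFILE,
    apply_dedup_filters,
    build_profile_msa,
    classify_call,
    conserved_window_gap_filter,
    extend_orf,
    identity_cluster,
    pairwise_identity,
    select_initiation_codon,
)
from chemorep.synth import make_donor_cds


def _region(scaffold, start, end, strand="+", **kw):
    defaults = dict(query_id="q", evalue=1e-40, bitscore=200.0, n_hits=1,
                    category="V1R", frames=(1,), frame=1)
    defaults.update(kw)
    return BestHitRegion(scaffold_id=scaffold, strand=strand, start=start,
                         end=end, **defaults)


@pytest.fixture(scope="module")
def donor():
    rng = np.random.default_rng(42)
    # 300 aa + stop, conserved window at 274, ~10% diverged from the profile
    return make_donor_cds(rng, template=V1R_PROFILE.reference_seq, divergence=0.1)


class TestExtendOrf:
    def test_clean_planted_gene_recovered_exactly(self, donor):
        seq = "C" * 60 + "TAA" + donor + "G" * 60
        asm = GenomeAssembly({"s": seq})
        # hit covers an interior slice of the CDS, in frame
        cand = extend_orf(_region("s", 63 + 30, 63 + 330), asm)
        assert cand.start == 63 and cand.end == 63 + len(donor)
        assert cand.protein == str(Seq(donor).translate())[:-1]
        assert cand.evidence == []

    def test_internal_stop_recorded_as_disruption(self, donor):
        broken = donor[:450] + "TAA" + donor[453:]
        seq = "C" * 60 + "TAA" + broken + "G" * 60
        asm = GenomeAssembly({"s": seq})
        cand = extend_orf(_region("s", 63, 63 + 900), asm)
        assert any(e.startswith("internal-stop") for e in cand.evidence)

    def test_open_reading_to_scaffold_end_is_contig_end(self, donor):
        # drop the stop codon and everything after: reading runs off 3'
        seq = "C" * 60 + "TAA" + donor[:600]
        asm = GenomeAssembly({"s": seq})
        cand = extend_orf(_region("s", 63, 63 + 300), asm)
        assert "contig-end-3prime" in cand.evidence

    def test_region_outside_scaffold_rejected(self, donor):
        asm = GenomeAssembly({"s": "ACGT" * 30})
        with pytest.raises(ValueError):
            extend_orf(_region("s", 0, 500), asm)


class TestClassify:
    def _call(self, protein="M" + "A" * 300, evidence=()):
        return GeneCall("c1", "V1R", "candidate", "s", "+", 0, 3 * len(protein),
                        protein, list(evidence))

    def test_clean_full_orf_intact(self):
        assert classify_call(self._call()).status == "intact"

    def test_partial_orf_at_contig_end_truncated(self):
        c = classify_call(self._call(protein="M" + "A" * 100,
                                     evidence=["contig-end-3prime", "short-cds"]))
        assert c.status == "truncated"

    def test_frameshift_is_pseudogene(self):
        c = classify_call(self._call(evidence=["frameshift@10"]))
        assert c.status == "pseudogene"

    def test_short_clean_orf_is_pseudogene(self):
        c = classify_call(self._call(protein="M" + "A" * 100, evidence=["short-cds"]))
        assert c.status == "pseudogene"


def _toy_profile(atg_window=40):
    # reference: 10 residues, anchor at residue 5 (R), window columns 7..9
    return FamilyProfile(
        family="V1R", reference_id="ref", reference_seq="WWWWRWWWKK",
        anchor_index=5, atg_window=atg_window, conserved_window_span=(7, 9),
        min_cds_aa=1, min_final_aa=1, max_window_gaps=2,
    )


class TestInitiationCodonSelection:
    def test_most_upstream_start_within_window(self):
        # candidate has Ms at positions -45, -30, -10 relative to the anchor
        prof = _toy_profile()
        nterm = ["A"] * 50
        for pos in (-45, -30, -10):
            nterm[50 + pos] = "M"
        cand = "".join(nterm) + "RWWWKK"
        msa = {"ref": "-" * 46 + prof.reference_seq, "c": cand}
        chosen = select_initiation_codon(msa, prof)
        assert chosen["c"][1] == 20  # trimmed to the M at position -30
        assert chosen["c"][0].startswith("M")
        assert len(cand) - chosen["c"][1] == len(chosen["c"][0])

    def test_zero_length_nterm_discarded(self):
        prof = _toy_profile()
        # candidate's first residue sits at the anchor column
        msa = {"ref": prof.reference_seq, "c": "----RWWWKK"}
        assert select_initiation_codon(msa, prof) == {}

    def test_start_outside_window_discarded(self):
        prof = _toy_profile(atg_window=27)
        nterm = ["A"] * 34
        nterm[34 - 28] = "M"  # only M is at -28, outside -27..0
        msa = {"ref": "-" * 30 + prof.reference_seq, "c": "".join(nterm) + "RWWWKK"}
        assert select_initiation_codon(msa, prof) == {}

    def test_missing_anchor_is_error(self):
        prof = _toy_profile()
        with pytest.raises(ValueError, match="reference"):
            select_initiation_codon({"c": "MAAA"}, prof)


class TestConservedWindowFilter:
    def _msa(self, cand_window):
        prof = _toy_profile()
        # window columns are reference residues 7..9
        cand = "MWWWRW" + cand_window + "K"
        return prof, {"ref": prof.reference_seq, "c": cand}

    def test_at_gap_threshold_removed(self):
        prof, msa = self._msa("--W")  # 2 gaps = max_window_gaps
        assert conserved_window_gap_filter(msa, prof) == []

    def test_below_gap_threshold_retained(self):
        prof, msa = self._msa("-WW")  # 1 gap < 2
        assert conserved_window_gap_filter(msa, prof) == ["c"]

    def test_short_candidate_removed_by_length_gate(self):
        prof = _toy_profile()
        prof = FamilyProfile(**{**prof.__dict__, "min_final_aa": 11})
        msa = {"ref": prof.reference_seq, "c": "MWWWRWWWWK"}  # 10 aa < 11
        assert conserved_window_gap_filter(msa, prof) == []

    def test_paper_scale_windows_on_real_profile(self, donor):
        # a donor missing the conserved block shows >= 7 gaps in the window
        prot = str(Seq(donor).translate())[:-1]
        deleted = prot[:273] + prot[288:]
        msa = build_profile_msa({"full": prot, "del": deleted}, V1R_PROFILE)
        kept = conserved_window_gap_filter(msa, V1R_PROFILE)
        assert "full" in kept and "del" not in kept


class TestDedupFilters:
    def _mk(self, cid, scaffold, protein, status="intact", evidence=()):
        return GeneCall(cid, "V1R", status, scaffold, "+", 0, 3 * len(protein),
                        protein, list(evidence))

    def test_short_contig_rule_i(self):
        asm = GenomeAssembly({"short": "A" * 900, "long": "C" * 1500})
        calls = [self._mk("a", "short", "M" + "A" * 300),
                 self._mk("b", "long", "M" + "C" * 300)]
        kept, log = apply_dedup_filters(calls, asm)
        assert [c.call_id for c in kept] == ["b"]
        assert any(l.startswith("i\t") for l in log)

    def test_identical_intact_pair_rule_iii(self):
        asm = GenomeAssembly({"s1": "A" * 2000, "s2": "C" * 2000})
        p = "M" + "ACDEF" * 60
        kept, log = apply_dedup_filters(
            [self._mk("a", "s1", p), self._mk("b", "s2", p)], asm
        )
        assert len(kept) == 1
        assert any(l.startswith("iii\t") for l in log)

    def test_truncated_contained_in_intact_rule_iii(self):
        asm = GenomeAssembly({"s1": "A" * 2000, "s2": "C" * 2000})
        full = "M" + "ACDEF" * 60
        part = full[: len(full) // 2]
        kept, _ = apply_dedup_filters(
            [self._mk("a", "s1", full),
             self._mk("t", "s2", part, status="truncated",
                      evidence=["contig-end-3prime"])],
            asm,
        )
        assert [c.call_id for c in kept] == ["a"]

    def test_complementary_truncated_pair_merges_rule_iv(self):
        asm = GenomeAssembly({"s1": "A" * 2000, "s2": "C" * 2000})
        rng = np.random.default_rng(17)  # aperiodic protein: unique overlap
        full = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), 300))
        a = self._mk("a", "s1", full[:200], status="truncated",
                     evidence=["contig-end-3prime"])
        b = self._mk("b", "s2", full[150:], status="truncated",
                     evidence=["contig-end-5prime"])
        kept, log = apply_dedup_filters([a, b], asm)
        assert len(kept) == 1  # each merge reduces the count by exactly 1
        merged = kept[0]
        assert merged.status == "intact"
        assert merged.protein == full
        assert any(l.startswith("iv\t") for l in log)

    def test_embedded_contig_rule_ii(self):
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), 1200))
        asm = GenomeAssembly({"small": core, "big": "ACGTAC" * 50 + core + "GGCCA" * 60})
        p = "M" + "ADEFG" * 60
        kept, log = apply_dedup_filters(
            [self._mk("a", "small", p), self._mk("b", "big", p)], asm
        )
        # the call on the shorter, embedded contig is dropped
        assert [c.call_id for c in kept] == ["b"]
        assert any(l.startswith("ii\t") for l in log)


class TestIdentityCluster:
    def test_identical_pair_one_group(self):
        groups = identity_cluster({"a": "MAAA", "b": "MAAA"}, 0.9)
        assert len(groups) == 1

    def test_single_linkage_chains_through_intermediate(self):
        # a-b and b-c above threshold, a-c below: one group by single linkage
        rng = np.random.default_rng(23)
        base = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVY"), 99))
        def mutate(s, positions):
            s = list(s)
            for p in positions:
                s[p] = "W"  # W never appears in base
            return "".join(s)
        b = base
        a = mutate(base, range(5, 45, 5))  # 8 substitutions in the first half
        c = mutate(base, range(55, 95, 5))  # 8 in the second half
        prots = {"a": a, "b": b, "c": c}
        # verify the premise with the package's own identity, then cluster
        assert pairwise_identity(a, b) >= 0.9
        assert pairwise_identity(b, c) >= 0.9
        assert pairwise_identity(a, c) < 0.9
        groups = identity_cluster(prots, 0.9)
        assert len(groups) == 1
        # brute-force union-find over the identity matrix agrees
        assert _brute_groups(prots, 0.9) == 1

    def test_all_distinct_yield_singletons(self):
        prots = {"a": "MAAAAAAA", "b": "MCCCCCCC", "c": "MDDDDDDD"}
        groups = identity_cluster(prots, 0.9)
        assert len(groups) == 3

    def test_representative_is_longest_then_lexicographic(self):
        groups = identity_cluster({"b": "MAAAA", "a": "MAAAA", "z": "MAAA"}, 0.7)
        assert groups[0]["representative"] == "a"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            identity_cluster({}, 0.8)


def _brute_groups(prots, thr):
    ids = list(prots)
    adj = {i: set() for i in ids}
    for i in ids:
        for j in ids:
            if i < j and pairwise_identity(prots[i], prots[j]) >= thr:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), 0
    for i in ids:
        if i in seen:
            continue
        comps += 1
        stack = [i]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x])
    return comps
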