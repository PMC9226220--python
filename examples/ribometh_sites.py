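"""RiboMeth-seq MethScores: recovering planted 2'-O-methylation sites.

Simulates alkaline fragmentation of 20,000 rRNA molecules where 20
methylated riboses protect their 3' bond (20% of baseline cleavage
retained), size-selects fragments to the 30-200 nt library window, counts
5'/3' fragment ends per bond, and computes per-base MethScores.  A second
run with weakened protection (0.6) stands in for the knockout and is
compared site-by-site.
"""

from ervkit import (
    RiboSimSpec,
    compare_methscores,
    detect_sites,
    methscore,
    simulate_fragments,
)

wt = simulate_fragments(RiboSimSpec(seed=1, n_molecules=20_000))
track = methscore(wt.profile(), window=6)

top = detect_sites(track, 20)
hits = set(top) & set(wt.sites)
print(f"planted sites: {len(wt.sites)}, recovered in top-20 MethScores: {len(hits)}")
print(f"mean MethScore at planted sites:  {track.loc[wt.sites, 'score'].mean():.3f}")
background = track.loc[track["coverage_ok"], "score"].drop(wt.sites)
print(f"mean MethScore elsewhere:         {background.mean():.3f}")

ko = simulate_fragments(
    RiboSimSpec(seed=2, n_molecules=20_000, protection=0.6, methylated_sites=wt.sites)
)
res, table = compare_methscores(
    track, methscore(ko.profile(), window=6), sites=wt.sites, side="greater"
)
print(f"\nKO (weaker protection) vs WT at the planted sites:")
print(f"median score change (KO - WT): {table['delta'].median():+.3f}")
print(f"one-sided signed-rank p:       {res.p_value:.2e}")
print("a negative median delta with small p detects the methylation loss.")
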