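# kinevo

Tools for studying how protein-kinase substrate specificity evolves.

Serine/threonine kinases recognise their substrates partly through a few
residues flanking the phospho-acceptor — the kinase-substrate motif (e.g.
R-R-x-S/T for PKA, S/T-P-x-K for CDKs). The eukaryotic kinase superfamily is
classified hierarchically into groups, families and subfamilies, and a natural
question is *when* in this expansion new target motifs arose. `kinevo`
implements the full analytical toolkit for that question:

* **Divergence scoring** between sister clades of a kinase-domain phylogeny.
  Each alignment column gets a score

  ```
  S = RC − AC · p(AC)
  ```

  where RC (recent conservation) is the within-clade conservation of the
  column on a substitution-matrix similarity scale rescaled to [0, 1], AC is
  +1/−1 according to whether the reconstructed ancestral residues of the two
  sister clades match, and p(AC) is the confidence of that call taken from the
  sister clade's ancestral posterior. A column fixed for different residues in
  the two clades, with confident ancestors, scores S = 2. Scores above the
  95th percentile at a level are "switches"; per-domain-position switch counts
  are tested for enrichment in functional categories (catalytic, substrate-
  proximal, regulatory, ...) with one-sided Fisher and Mann-Whitney tests.
* **Marginal ancestral sequence reconstruction** (Felsenstein pruning,
  inside–outside marginals, LG or Poisson models) so the scoring pipeline runs
  without external reconstruction software; externally produced posteriors can
  be supplied as a TSV table instead.
* **Specificity models**: position weight matrices (20 residues × 14 flank
  positions) from 15-mer target sites, compared with the Frobenius distance
  ‖A − B‖F within/between groups, families and subfamilies, with a
  specificity-divergence threshold derived by subsampling targets of
  well-characterised kinases (n = 25 subsamples from kinases with ≥ 50 sites).
* **Phosphorylation-motif analysis**: shuffled-flank backgrounds (centre S/T
  fixed, 10 shuffles per site), greedy motif-x-style discovery (p < 1e−6,
  ≥ 20 occurrences), a superset-conditioned binomial enrichment p-value,
  cross-species motif filtering with synonym classes {R,K}, {D,E}, {L,I,V,M},
  and phosphoproteome coverage.
* **Dating kinase-unit origins**: equal-rates two-state Markov (Mk) model
  fitted by maximum likelihood on a species tree from a presence/absence
  matrix, marginal ancestral presence probabilities, origin-node calling with
  a most-recent-common-ancestor rule for multiple origins, and age assignment
  from a divergence-time table.
* **Comparative statistics**: phylogenetic independent contrasts, regression
  through the origin, Blomberg's K (permutation test) and Pagel's λ
  (likelihood-ratio test).
* **Synthetic data generators** for every input: family alignments evolved on
  a tree with implanted specificity-determining substitutions, PWM-derived
  target sites, motif/background phosphoproteome mixtures, Mk binary traits
  and correlated Brownian traits — so the whole pipeline is testable without
  any database downloads.

## Worked example

Simulate a family alignment on a two-clade tree (20 leaves per clade, 200
columns) with four implanted clade-A-specific substitutions, then recover
them with the divergence score:

```python
import numpy as np
from kinevo.synthetic_data import (FamilySimulationSpec,
                                   simulate_family_alignment, two_clade_tree)
from kinevo.divergence_scoring import (select_focal_clade,
                                       select_sister_clade,
                                       divergence_scores, call_switches)

tree = two_clade_tree(20)
rng = np.random.default_rng(1)
cols = sorted(int(c) for c in rng.choice(200, size=4, replace=False))
spec = FamilySimulationSpec(
    tree=tree, root_length=200, branch_rate=0.05,
    implanted_switches=[("cladeA", c, "W") for c in cols], seed=1)
aln, anc, truth = simulate_family_alignment(spec)

cand = select_focal_clade(tree, aln.labels, "cladeA", "family")
comp = select_sister_clade(tree, cand, aln.labels)
table = divergence_scores(comp, aln, anc)
profile = call_switches([table], "family", n_positions=200)

print("implanted columns:", cols)
print(f"switch threshold s(95) = {profile.threshold:.3f}")
print("called switch columns:",
      sorted(p - 1 for p, c in profile.counts.items() if c > 0))
```

Output:

```
implanted columns: [93, 101, 150, 190]
switch threshold s(95) = 1.614
called switch columns: [9, 93, 101, 111, 123, 130, 150, 183, 184, 190]
```

All four implanted columns are called (they score the maximum S = 2: perfectly
conserved within clade A, RC = 1, and fixed for a different residue than the
certain clade-B ancestor, AC = −1 with p(AC) = 1). The remaining calls are
substitutions that happened to become fixed between the clades during the
neutral simulation — exactly the kind of event the score is designed to flag;
the implanted ones are simply guaranteed.

A command-line interface mirrors the library
(`kinevo simulate|anc|score|pwm|motifs|date|pic|signal`); run
`kinevo --help` for details.

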