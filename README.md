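# gipscape

Computational companion toolkit for studying GIP/MZT1-family proteins — the
smallest γ-tubulin-complex components (~7–8 kDa) — and their role at the plant
nuclear envelope. The package bundles the four desk analyses such a study
needs, plus synthetic-data generators with known ground truth so every stage
is testable without external downloads:

1. **Degenerate-motif scanning** (`gipscape.signature`). The GIP family is
   defined by a 34-position PROSITE-style signature (residue classes,
   wildcards, and a single invariant glycine at element 24). The module
   parses the motif grammar, scans protein sequences case-insensitively for
   fixed-width matches, classifies sequence sets, and locates the glycine
   anchor: for a match starting at residue *s*, the anchor sits at
   *s* + 23 (e.g. a match at residue 19 puts it at residue 42).
2. **Percent identity and neighbor joining** (`gipscape.identity_phylo`).
   All-vs-all global alignment (Needleman–Wunsch, BLOSUM62, affine gaps
   10/0.5), percent identity over alignment columns with terminal gaps
   excluded, distances d = 1 − id/100, and a Saitou–Nei neighbor-joining
   tree serialized to Newick. NJ is consistent: on additive distance
   matrices it recovers topology and branch lengths exactly.
3. **CD spectrum unmixing** (`gipscape.cd_unmix`). Far-UV circular-dichroism
   spectra in mean residue ellipticity (MRE, deg·cm²·dmol⁻¹) are decomposed
   into secondary-structure fractions by constrained ridge regression:
   minimize ‖θ − B f‖² + α‖f‖² subject to f ≥ 0 and Σf = 1, with α chosen
   by GCV if requested. Includes the millidegree → MRE conversion
   θ/(10·l·C·N_res) and a packaged synthetic 3-class basis.
4. **NPC spatial statistics** (`gipscape.npc`). Nearest-neighbor distances
   of pore-center point patterns in a rectangular window, distance-bin
   fractions, densities per μm² and condition ratios, a seeded two-sample
   permutation test on mean NN distance, and an isoperimetric circularity
   metric 4πA/P² for nuclear contours.

`gipscape.synthetic` generates signature-conformant protein families at
controlled divergence (Poisson substitutions per site, optionally
signature-preserving), break-one-position decoys, noisy basis mixtures, and
CSR / hard-core / Thomas-cluster point patterns. `gipscape.pipeline` owns
FASTA/Newick/CSV/JSON I/O, 1-based residue-region arithmetic, and a
schema-validated, manifest-checksummed simulate → scan → phylo driver.

## Worked example

```bash
$ gipscape simulate family --n-leaves 6 --rate 0.2 --seed 3 --out fam.faa
wrote 6 sequences to fam.faa; true tree to fam.nwk

$ gipscape scan --fasta fam.faa --out matches.tsv && head -3 matches.tsv
6 matches over 6 sequences -> matches.tsv
seq_id  start  end  matched_subsequence                 anchor_position
t1      19     52   VFFNVCKLLDRDSVKNIEMMWPRGGAAGTVANVG  42
t2      19     52   VFTNLRKNLDGDIVKNIEYMGPQGGAAGHLANVG  42

$ gipscape phylo --fasta fam.faa --reference t1 --newick tree.nwk --identities id.tsv
t1 shares 64 to 70% identity with the other 5 sequences
wrote id.tsv and tree.nwk

$ gipscape simulate spectrum --fractions 0.82,0.04,0.14 --noise-sd 300 --seed 2 --out spec.csv
$ gipscape cd-fit --spectrum spec.csv --alpha auto --out frac.json
estimated fractions: 82% helix, 4% sheet, 14% other (rms residual 302.7 MRE) -> frac.json
```

Each family member carries the signature (every leaf matched, with the
invariant glycine at residue 42 given the 18-residue flank used by the
generator); the identity range tightens or widens with the substitution
rate; and the unmixer recovers the known helix-dominated composition from a
noisy synthetic spectrum. For pore patterns:

```bash
$ gipscape simulate points --process hard-core --intensity 50 --hard-core-distance 60 --seed 1 --out wt.csv
wrote 100 points to wt.csv (window sidecar wt.window.json)
$ gipscape simulate points --process thomas --intensity 87.5 --seed 2 --out mut.csv
wrote 132 points to mut.csv (window sidecar mut.window.json)
$ gipscape npc --wt wt.csv --mut mut.csv --perms 9999 --seed 5
mean NN distance: wt 97.0 nm, mut 23.1 nm (p=0.0001); density ratio mut/wt = 1.32
```

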