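# argbox

Individual-information modelling, discovery and genome scanning of ArgR
operator sites ("ARG boxes") in *Streptomyces coelicolor*.

ArgR is the arginine-responsive repressor of arginine and pyrimidine
biosynthesis in bacteria. In *Streptomyces* it binds imperfectly palindromic
~20-nt operators, arranged either as a single box or as two tandem boxes
separated by 0 or 1 nt. This package rebuilds the *S. coelicolor* ARG box
model from the 44 experimentally supported boxes (band-shift assays; 37
well-conserved boxes form the training set, packaged here as a plain-text
table) and provides the full analysis toolchain around it, for
microbiologists and regulatory-genomics researchers who want to score,
predict or simulate ArgR binding sites.

## The model

From an alignment of *n* binding sites of width *L*, with per-position base
frequencies *f(b, l)*:

- small-sample correction: *e(n) = 2 − E[H_obs]*, the expected upward bias
  of the plug-in entropy of *n* uniform draws (computed by exact
  multinomial enumeration);
- per-position weights (bits): *Riw(b, l) = 2 + log₂ f(b, l) − e(n)*;
- score of a sequence *s*: *Ri(s) = Σ_l Riw(s_l, l)*;
- model conservation: *Rsequence = Σ_l [2 − H(l) − e(n)]*, which equals the
  mean *Ri* of the training alignment exactly.

Because the operator is a palindrome bound by a symmetric ArgR oligomer,
the production model pools the training boxes with their reverse
complements before counting (`palindromic=True`, the default of
`argbox.argbox_model()`); this makes scores strand-symmetric and reproduces
the published per-box values.

Around the model:

- **Scanning** (`argbox.scanner`): both-strand sliding-window scan with
  exact upper-tail p-values from a dynamic program over the discrete
  log-odds score distribution under the scanned sequence's own 0-order
  composition, filtered by the published dual rule (p < 10⁻⁵ and
  Ri > 10.0 bits), tandem-site assembly and downstream-gene association.
- **Discovery** (`argbox.discovery`): palindrome-constrained EM motif
  discovery (ZOOPS and ANR occurrence models, optional discriminative
  background from a negative probe set).
- **Simulation** (`argbox.synthetic`): high-GC background genomes, planted
  boxes at controlled strength and architecture, labeled probe sets, and
  sensitivity/precision evaluation against the planted truth.

## Worked example

```python
import argbox

records = argbox.load_table1()            # the 44 packaged ARG boxes
model = argbox.argbox_model()             # 37 curated boxes + reverse complements

print(f"n={model.pfm.n}  Rsequence={model.rsequence:.2f} bits")
cons = argbox.consensus(model)
print(cons.residues, f"{argbox.ri_score(model, cons):.1f} bits")
argG = next(r for r in records if r.box_id == "AB.SCO7036_1")
print(argG.sequence.residues, f"{argbox.ri_score(model, argG.sequence):.1f} bits")
```

prints

```
n=74  Rsequence=10.06 bits
GTCTGCATGATCATGCAGAC 21.0 bits
CTTTGCATGGTCATGCGTAA 17.4 bits
```

`Rsequence` ≈ 10 bits says an average ARG box carries about ten bits of
information relative to random sequence; the consensus scores the maximal
21.0 bits, and the strong tandem box upstream of *argG* scores 17.4 bits
(published: 17.2). The same numbers are available from the shell:

```sh
argbox build --outdir out/model          # model.txt + logo.tsv
argbox score --fasta boxes.fa --outdir out/scores
argbox scan  --fasta genome.fa --outdir out/scan   # BED + site report
argbox simulate --n-sites 50 --strength fixed_ri_target --ri-target 14 \
    --seed 3 --outdir out/sim
argbox evaluate --genome out/sim/genome.fasta --truth out/sim/truth.tsv \
    --outdir out/eval
```

Every command echoes its resolved configuration to `config.yaml` in the
output directory; reruns from the same configuration are bit-identical.

## Layout

- `src/argbox/seqio.py` — FASTA/BED/GFF3 I/O, coordinate conventions, strand utilities
- `src/argbox/boxdata.py` — the packaged box table, curation, site architectures
- `src/argbox/iimodel.py` — frequency matrices, e(n), Riw, Rsequence, Ri, logos
- `src/argbox/discovery.py` — palindromic ZOOPS/ANR EM motif discovery
- `src/argbox/scanner.py` — genome scanning, exact p-values, site assembly, gene association
- `src/argbox/synthetic.py` — synthetic genomes, planted truth sets, metrics
- `src/argbox/cli.py` — the `argbox` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
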