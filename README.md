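# casepy

Computer-assisted structure elucidation (CASE) of small organic molecules
from ¹³C-centric NMR data, as a Python library with a thin command-line
layer.

Given a molecular formula and a correlation table — ¹³C signals with
multiplicities, plus HSQC, HMBC and COSY links — `casepy` either recognizes
an already-known compound by matching its spectrum against a
structure-and-spectrum knowledge base (*dereplication*), or exhaustively
generates every constitutional isomer consistent with the data, predicts
each candidate's ¹³C spectrum, and ranks the candidates by agreement with
the experiment.  It is aimed at spectroscopists and cheminformaticians who
want an open, scriptable, fully offline backend for structure verification
and *de novo* elucidation experiments.

## What it computes

**Knowledge base.** A record couples a kekulized heavy-atom graph with its
assigned ¹³C spectrum.  Signals with identical shift δ and multiplicity
(attached-proton count) merge into one signal with an equivalence index *e*,
so that Σᵢ eᵢ = number of carbons.  From the records the package builds a
per-sphere HOSE-code shift library and an occurrence-statistics store keyed
by (1-ppm shift bin, multiplicity, element set).

**Dereplication.** Two spectra are compared by greedy closest-first unique
pairing of signals within a shift tolerance (optionally requiring equal
multiplicity/equivalence); the distance is the mean absolute deviation
d̄ = (1/n) Σ |δ_query − δ_ref| over matched pairs only.

**Fragments.** Every record is fragmented by spherical propagation (bonds
between carbon and hetero atoms are never cut; a start atom inside a ring
pulls in its whole fused ring system).  Each fragment's subspectrum becomes
a 280-bit string over 1-ppm bins on [−20, 260) ppm; a fragment survives
screening when all its bits fall inside the (optionally dilated) query bit
string, and survivors are ranked by size, then spectral deviation.

**Constraint detection.** For each query signal, the statistics store yields
hybridization candidates (states below a 1 % occurrence threshold are
discarded), forbidden neighbours (< 1 % occurrence), mandatory neighbours
(≥ 95 %), and a global hetero–hetero-bond permission (≥ 1 % of all bonds).
All thresholds are per-run parameters.

**Structure generation.** A deterministic backtracking search enumerates all
connected heavy-atom graphs satisfying valences, pinned hydrogen counts,
hybridization-consistent bond-order patterns (sp³ ⇒ all single, sp² ⇒ one
double, sp ⇒ one triple or two doubles), neighbour-element constraints,
HMBC/COSY proximity constraints (heavy-atom distance 1–2 / 1 by default),
the hetero–hetero-bond flag and good-/bad-list substructures, deduplicated
by canonical signature and truncated (flagged) at 500 solutions.

**Prediction and ranking.** Each candidate carbon is looked up in the HOSE
library at the deepest available sphere (6 → 1 fallback; unknown
environments stay unpredicted), and candidates are ordered by d̄ between
predicted and experimental spectra, ties by matched-signal coverage.

## Worked example

Elucidate a fixture compound from its (synthetically derived) correlation
table against the 220-record fixture knowledge base:

```python
from casepy import *
from casepy.fixtures import make_fixture_kb, FixtureSpec, correlation_set_for

kb = make_fixture_kb(FixtureSpec(seed=42))
stats = accumulate_statistics(kb)
library = build_hose_library(kb)

target = next(r for r in kb if r.molecule.to_smiles() == "CCOC(=O)C1=CC=CC=C1")
corr = correlation_set_for(target)          # 13C rows + HSQC/HMBC/COSY
mf = target.molecule.formula()              # C9H10O2

cons = detect_constraints([(c.id, c.shift, c.multiplicity) for c in corr.carbons],
                          mf, stats)
problem = build_problem(corr, mf, constraints=cons,
                        hhb_allowed=detect_hhb(mf, stats))
result = generate(problem)
ranking = rank_candidates(result.structures, target.spectrum, library)
```

Output of the session above:

```
knowledge base: 220 records
query signals : [(24.25, 3, 1), (69.59, 2, 1), (170.67, 0, 1), (123.82, 0, 1),
                 (120.96, 1, 2), (109.77, 1, 2), (113.48, 1, 1)]
generator: 1 candidate structure(s), truncated=False
rank 1: CCOC(=O)C1=CC=CC=C1  avg dev 0.00 ppm  matched 7/7
```

The seven query signals (shift, multiplicity, equivalence — the two
equivalence-2 entries are the symmetric aromatic CH pairs) admit exactly one
constitutional isomer under the detected constraints; its predicted spectrum
reproduces the query exactly, so it ranks first with zero average deviation
and full 7/7 signal coverage.

The same workflow is available from a shell:

```bash
casepy build-kb --seed 42 --out kbdir
casepy pipeline --query peaks.json --kb kbdir/kb.json \
       --library kbdir/library.json --stats kbdir/stats.json --out run
```

Each subcommand writes machine-readable results plus a `manifest.json` into
its run directory; re-running a manifest reproduces the outputs
bit-identically.  Two synthetic query documents
(`casepy.bundled_peaklist_path("testcase2_synthetic")`, `..."testcase15_synthetic")`)
illustrate the peak-list JSON schema, including edited-HSQC S+/S− sign
handling and explicit hetero-proton attachments.

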