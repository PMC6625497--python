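# Methods

## The problem

Bioinformatics analyses are long chains of file-transforming tools.  Two
failure modes dominate in practice: a stage is handed a file in the wrong
format or state (unsorted input to a duplicate marker, FASTA where an
alignment was expected) and fails hours into a run; and ad-hoc intermediate
naming breaks incremental re-execution, so a crashed workflow is rerun from
scratch.  `typedflow` addresses both with one design: workflows are
*expressions* whose metadata is checked as a whole before anything executes,
and whose intermediates are content-hash named and tracked by a make-like
engine with a persistent digest database.

## The workflow algebra

A pipeline expression is one of:

* `Source(paths, tags, values)` — user-named input files with declared tags;
* `Compose(upstream, stage)` — forward composition, written `expr >> stage`
  (left-associative, like a Unix pipe);
* `AllOf(parts)` — a bundle whose outputs are the concatenation of its
  members' outputs (built by `with_all`); `Select(parent, i)` picks one
  output of a multi-output expression (built by `split`);
* `Named(inner, names)` — `out(expr, names)`, copy rules from managed files
  to user-visible names.

A `Stage` declares required input tags, ordered output tags (the first fixes
the output file extension), transient tags (preserved from input when
present), semantic parameters, a thread/resource request, and a builder.
Construction never checks tags: `validate` is the single gate, mirroring the
separation between writing code and compiling it.  `compile_rules` refuses
to emit rules while an error diagnostic is outstanding, so the library-level
contract is "well-tagged or no rules".

### Tag semantics

Effective tags are computed bottom-up and closed under a user-declared
implication relation (least fixpoint; the closure operator is extensive,
monotone, and idempotent, and is property-tested against brute-force
reachability).  Three flow rules:

* *propagating* tags (e.g. `DeDuped`) hold on every node downstream of
  where they first appear;
* *transient* tags (e.g. `Sorted` through a duplicate marker) are preserved
  by a stage only if it declares them and they hold upstream;
* a bundle guarantees exactly the intersection of its members' tags.
  Intersection is the sound, under-promising choice: a consumer of a bundle
  can rely only on what every member provides.

Valued tags (e.g. `Referenced`, the reference-genome path) carry a value
downstream; the nearest upstream setter wins, and two members of a bundle
carrying different values for the same valued tag is an error rather than
last-wins, because silently mixing reference genomes is precisely the bug
class the validation exists to prevent.

Ontology terms (a bundled ~55-term format/data subset in a tabular dialect;
`.obo` accepted via obonet) enter the same machinery: attaching a tag to a
term installs implications from the tag to the term and from each term to
its parents, so a requirement stated at any ancestor level matches.

Tags are checked at the expression level only and never verified against
file bytes at run time — by design there is no runtime overhead and no
false confidence: the guarantee is relative to honest stage declarations.
The toy stages *do* defensively validate their input dialects, which is what
makes the validation-soundness property observable in tests.

## Naming

Managed outputs live under a configurable work directory (default
`_typedflow`) and are named `<digest>.<stage>.<ext>` (multi-output stages:
`<digest>.<stage>.<i>.<ext>`, 1-based).  The digest is SHA-1 over a
length-prefixed canonical serialization of the upstream paths (taken
relative to the work directory, so relocating it changes prefixes only),
the stage name, and the sorted semantic parameters; base32-lowercase,
truncated to 32 characters.  Hashing only input paths would let two
parameterizations of one stage collide, so stage identity and parameters
are folded in.  Threads and memory are excluded: changing parallelism must
never invalidate outputs.  Path collisions across distinct nodes are
checked at validation time and are a hard error.

## Compilation and the build engine

Compilation is a post-order traversal emitting one rule per composed stage
(outputs = managed paths, static dependencies = upstream outputs, action =
the stage builder closed over the node).  A seen-set keyed on the
output-path sequence deduplicates shared prefixes across concurrent
workflows; because names fold in stage identity and parameters, identical
key implies identical action.

The engine brings targets up to date with make-like semantics:

* **Up-to-date check** — a rule is skipped iff all outputs exist, the
  recorded rule fingerprint matches, and every recorded dependency's SHA-1
  content digest is unchanged (size+mtime as a fast path only).  Content
  digests, not mtimes, so copied or restored trees behave correctly.
* **Database** — JSON-lines, one entry per output, atomically rewritten
  after each completed rule.  An interrupted build resumes from the last
  completed rule; corrupt entries are dropped, degrading to rebuild, never
  to wrong reuse.
* **Early cutoff** — if a rebuilt file comes out byte-identical (e.g. a
  deleted intermediate regenerated), downstream digests still match and
  downstream rules are skipped.  Consequently the "descendants rebuild"
  minimality law is stated for content perturbations of inputs, where
  descendants genuinely change; it is tested against an independent
  graph-reachability oracle on randomized DAGs.
* **Dynamic dependencies** — actions may `ctx.need(paths)` mid-run; needed
  paths are built via their rule, via a matching one-wildcard *pattern
  rule* (the extrinsic escape hatch, e.g. `*.bam.bai` indices, explicit
  rules taking precedence and ambiguous matches an error), or must exist
  as plain source files.  All needs are recorded in the database.
* **Scheduling** — ready rules dispatch in lexicographic order of first
  output path; `jobs` worker threads run independent rules concurrently
  with results contracted (and tested) byte-identical to a serial run.
  First failure stops dispatch unless `keep_going` is set.  Static cycles
  are reported with the offending paths; dynamic cycles are caught via a
  per-thread rule stack.

## Executors

Builders never spawn processes directly; they pass an argv token list to
`ctx.run`, which the executor interprets.  `local` executes the tokens with
no shell.  `script` renders a POSIX shell job script with Torque-style
`#PBS -l nodes=1:ppn=<threads>,mem=<mb>mb[,walltime=<s>]` headers (one
renderer function; other dialects would substitute there).  Script mode
defaults to *dry*: the script is written for inspection and executed
locally, exercising the full generation path with no scheduler.  *submit*
mode invokes a configured submission command and polls a sentinel file the
script touches on completion — sentinel polling was chosen because it needs
no queue-specific status protocol.

## Synthetic data and the toy stage pack

The generator (`gen_reads`) emulates a minimal resequencing study: uniform
random contigs (default 3 × 300 bp), error-free reads (default 200 × 40 bp)
sampled from a sample genome that differs from the reference at planted SNPs
(default 2 per contig, each guaranteed two covering reads), plus 20%
appended exact duplicate reads.  The ground truth — variants, per-read
origins, and the duplicate set under the all-but-first-at-a-position rule —
is recorded as JSON next to the data, so downstream checks are exact rather
than statistical.  Defaults were sized so a full linear pipeline runs in a
fraction of a second while leaving every property (coverage, duplication,
multi-contig behaviour) non-degenerate.

The toy stages are line-oriented text transformations invoked as
subprocesses through the executor layer (`toytools.py`, standard library
only, executed by file path so spawning stays cheap): exact/seeded
minimum-Hamming read placement (`align`; non-overlapping 12-mer seeds, at
most 25% mismatches, leftmost tie-break — mismatch tolerance is required
because variant-bearing reads cannot exact-match the reference), sorting by
(contig, position, read id), duplicate marking/removal by position,
pileup-based calling of positions where ≥2 reads agree on a non-reference
base, round-robin FASTA sharding, shared-k-mer scoring with top-m
extraction, majority-vote assembly from origin-annotated reads, and
concatenation (optionally sorted by header — the shard-count-invariant
gather used in the scatter–gather example).  The alignment dialect is a
tab-separated BAM stand-in with a magic header; the call output keeps the
minimal 8-column VCF shape.

What the toys deliberately do not model: sequencing error, quality scores,
paired-end constraints, indels, repeats long enough to confuse a 12-mer
seed, or binary container formats.  Passing tests therefore demonstrate the
*framework's* guarantees — validation soundness, minimal rebuilds,
determinism, executor transparency — on faithful miniature workloads; they
say nothing about the biological fidelity of any real aligner or caller.

## Numerical and design choices

* SHA-1/base32/32-char naming is fixed so managed names are stable across
  runs and platforms; the algorithm sits behind one function.
* Dispatch order, chunk ordering (parent output order), duplicate
  tie-breaks (lexicographically first read id), and hit ranking (score
  descending, subject id ascending) are all deterministic so byte-level
  comparisons are meaningful.
* Diagnostics are collected exhaustively rather than fail-fast, and carry
  the stage path (repeats disambiguated by index) plus the missing tags,
  renderable as text or JSON.
* Valued-tag shadowing is nearest-setter-wins; re-setting mid-pipeline is
  permitted and documented rather than an error.
* Degenerate inputs: empty sources, empty bundles, zero-output stages, and
  extension-less first output tags are construction/definition errors;
  empty ontology files load as empty ontologies; `close({}) == {}`.

## Limitations

Length-indexed output arity checking is out of scope: arity mismatches
between `out()` names and expression outputs are caught, but a builder
producing the wrong number of files surfaces only at build time.  Dynamic
workflows require the two-phase idiom (run, inspect, construct, run) rather
than dynamic-arity stages.  The scheduler offers no remote caching, no
daemon mode, and only the Torque header dialect; live queue submission is
implemented only as script emission plus sentinel polling.
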