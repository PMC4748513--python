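# Methods

This note documents the models and procedures behind `cigflow`: the pattern
catalogue, the BPMN interchange dialect, the recognition algorithm, the
per-language mappings, and the trace semantics used for validation —
including the numerical/structural choices made where the design was
genuinely open, and what the bundled fixtures do and do not show about
real guideline models.

## Pattern catalogue

The catalogue (`data/patterns.yaml`) encodes the 43 workflow control
patterns with a three-valued suitability label for the guideline domain:
`yes` (task structures of this kind occur in guideline text), `no`
(dismissed on principled grounds — multiple concurrent instances of a
task, multiple execution threads, unstructured loops/models, concurrent
execution with cancellation after synchronization), and `unknown` (no
supporting example found, but not ruled out). Both `yes` and `unknown`
count as *relevant*: 19 + 3 = 22 patterns, i.e. 51 % of the catalogue
after rounding. For the relevant patterns the catalogue also records
implementability in Asbru and PROforma: `direct`, `workaround`
(implementable only with a significant number of auxiliary variables), or
`not_implementable` (the pattern's rationale cannot be expressed). The
split/join pairs #2–#3, #4–#5 and #6–#7 are stored as separate rows with
identical labels but treated as one composite usage scheme by the
recognizer and emitters, reporting the split id as primary.

## BPMN interchange dialect

The reader/writer supports exactly the subset the relevant patterns need:
tasks; exclusive, parallel, inclusive and event-based gateways; none and
message start events; intermediate message catch events; none and
terminate end events; ad hoc sub-processes (with `ordering` and a
completion condition, and optional internal sequence flows expressing a
partial order); conditioned and default sequence flows. Any other element
raises an unsupported-construct error — silent dropping would corrupt the
downstream semantics. Diagram-interchange sections are ignored on read and
never written. Any namespace prefix bound to the BPMN 2.0 definitions
namespace is accepted; output uses the `bpmn` prefix.

Three design points deserve explanation:

* **Trigger associations.** BPMN does not fix how the task raising a
  signal relates to the intermediate message event consuming it. The
  dialect stores a dedicated association (task → event) and accepts either
  `bpmn:association` artifacts or `bpmn:messageFlow` elements on read; it
  writes associations. A `cig:persistent` extension attribute on the event
  distinguishes the persistent (#24) from the transient (#23) trigger.
* **Annotation convention.** Several patterns are under-determined by pure
  control flow in BPMN: milestone (#18), cancel activity/case/region
  (#19/#20/#25), critical section (#39), interleaved parallel routing
  (#17), discriminator and partial join (#9/#30), implicit termination
  (#11 — shape-identical to a plain sequence). These are recognized from a
  `cig:pattern` extension attribute placed on the region's entry node by
  the fixture generator (with `cig:quorum` giving the N of an
  N-out-of-M join). This is an explicit dialect convention, not an
  inference.
* **Conditions are opaque strings**, as in BPMN itself. A mini boolean
  grammar (identifier comparisons such as `condition="yes"`,
  `completed(task)` state predicates, `and`/`or`/`not`) is parsed when it
  applies, letting the emitters negate conditions, derive a default
  branch's condition as the negated disjunction of its siblings, and prove
  mutual exclusion syntactically (same identifier compared against
  different literals, or literal negation). Everything else is copied
  verbatim and logged in the post-editing report — condition
  formalization is inherently manual.

## Structuredness and recognition

A structured process is one where every split gateway has a matching join
of the same kind closing a single-entry/single-exit (SESE) region, with
regions properly nested; loops are structured post-test loops (an
exclusive-gateway loop entry, a body, and an exclusive-gateway exit with a
conditioned back edge). Validation and decomposition share one
recursive-descent region parser:

1. Back edges are identified first by iteratively peeling each strongly
   connected component at its unique entry node (a loop-nesting-forest
   construction); a component with multiple entries is an arbitrary,
   non-structured cycle and is reported as a violation.
2. On the resulting acyclic skeleton, sequences are walked node by node; a
   diverging gateway opens a block whose join is found by walking every
   branch (recursing through nested blocks and loops) until a converging
   gateway; kind mismatches, branches escaping to the process end, edges
   entering a region from outside, and non-gateway merge nodes are
   reported with the offending node.
3. Deferred choice is the one asymmetric case: BPMN has no converging
   event-based gateway, so the dialect closes a #16 region with an
   exclusive merge.

Labelling assigns each non-leaf region at most one pattern identity:
annotation first, then structural rules (gateway kind for blocks, loop,
sequential ad hoc sub-process, trigger association at process level,
terminate end event, sequence). A top-level sequence that only wraps
start/end events around one structural region inherits that region's label
at the wrapper's span, so a single-pattern model is reported as exactly
one whole-process instance. Regions that fit no rule are reported as
`unknown_fragment`, never guessed. A lone task inside a branch is not
reported as a sequence; #1 requires at least two ordered elements.

## Per-language mappings

The emitters walk the region tree and dispatch per pattern; the tables in
the module docstrings of `asbru.py` and `proforma.py` give the full
mapping. Choices worth recording:

* **Asbru exclusive choice** uses the declarative encoding: an `any-order`
  parent with `wait-for one` and mutually exclusive filter preconditions
  on the alternatives. The parent's completion relies on `wait-for one`
  alone; no additional complete condition is emitted.
* **Asbru workarounds** (#18 milestone, #24 persistent trigger, #25 cancel
  region — the `+/-` cells) use one auxiliary boolean variable per
  milestone/trigger, set by a silent `single_action` plan at the source
  and tested in the target's filter precondition; this is the minimal
  such scheme. Every workaround adds a `needs_postediting` entry; direct
  (`+`) patterns add none unless a condition string was unformalizable.
* **PROforma joins**: the language has no join element, so the post-join
  component receives scheduling constraints on all branch tails; for a
  single-selection decision, completion of a *discarded* branch is
  vacuous, which makes the same rule serve the simple merge.
* **PROforma persistent trigger**: the intermediate message event is not
  materialized; the target inherits its scheduling constraint from the
  nearest preceding non-event task and gets a `wait_condition` on
  completion of the triggering task. The event trigger on the triggering
  task is emitted only when the source model has a start message event.
  The transient trigger uses an event trigger on the target instead.
* **Refusals**: #23 in Asbru, and #17/#39/#40 in PROforma (interleaving
  one task at a time cannot be expressed without enumerating
  permutations, which contradicts the patterns' rationale) raise before
  any output is produced.
* **Multi-choice in PROforma** becomes a multiple-selection decision and
  is always flagged for post-editing: synchronizing the merge over
  non-taken branches needs manual refinement.

## Trace semantics

Validation mirrors how one would test the implementations in the native
engines, but in a controlled, exhaustive form. Both emitted models compile
onto a single executable intermediate — a *task system* of lifecycle
automata (pending → running → done, plus cancelled/discarded) with:
start-after dependencies; selectors (exclusive or subset choices, which
also encode condition guards and loop iteration counts); mutex groups
(one-at-a-time execution of `any-order` blocks); quorum gates; and
cancellation scopes. `enumerate_traces` explores every interleaving by
depth-first search and records the visible event sequences; gateways,
events, decisions and auxiliary variable-setting plans are silent, so
traces contain clinical actions only.

Numerical/semantic choices, each applied identically on the reference
side:

* Conditions are free booleans: both valuations are explored, except
  `completed(task)` predicates (and auxiliary trigger/milestone
  variables), which are structural dependencies.
* Loops are unrolled to `loop_bound` (default 2) with at-least-once
  semantics, matching the post-test loop encoding; iteration counts
  1..bound are enumerated.
* Cancellation may fire while at least one task of its scope is running:
  running tasks emit `cancelled`, pending scope tasks are withdrawn
  silently, and flow continues after the scope (for cancel case, nothing
  remains to continue). Cancellation of an idle scope is not modelled, so
  every `cancelled` event is preceded by its `started`.
* A multi-choice selects a non-empty subset of branches (at least one
  alternative is assumed applicable).
* Deferred choice is environment-resolved: one branch per trace, no
  condition involved; its trace set coincides with the exclusive choice's,
  the difference being where the resolution happens, not what is
  observable in complete traces. Likewise, the transient trigger's signal
  loss and the discriminator's early release are not observable in the
  finite complete traces of the canonical fixtures (the discriminator
  region has no downstream task), so those cells validate against the
  same trace sets as their persistent/parallel counterparts; the
  distinguishing machinery (event consumption, quorum gates) is
  nevertheless in place.
* Bound exhaustion sets `truncated` on the result rather than silently
  dropping traces, and truncated sets are only comparable at equal
  bounds.

`reference_traces` generates the expected sets in closed form with small
combinatorial helpers (interleavings, block permutations under a partial
order, prefix truncations), independently of the region parser and of both
compilers. The test suite adds a third, fully independent path: a
brute-force interleaver that enumerates all permutations of the lifecycle
event multiset and filters them by declarative per-pattern constraints;
its counts must match both the reference and the enumerated models on all
loop-free fixtures.

## Fixtures: what they emulate and what they do not

The fixture generator produces the canonical structured model of each
relevant pattern with deterministic ids derived from pattern id and role
(`p4_xor_split`), so serialized XML is byte-stable. Defaults follow the
worked examples: two branches (three for interleaved routing and the
partial join), task names `action_A`, `action_B`, …, exclusive-choice
conditions `condition="yes"` and its negation, a follow-up-style loop exit
condition, and an ad hoc completion condition meaning "all contained
activities completed exactly once" (an approximation — it relies on the
performer activating each activity exactly once). Compositions substitute
one fixture for a task of another, preserving structuredness; trigger
fixtures cannot be nested because they span two branches.

These models exercise every mapping rule and the full implementability
matrix, but they are schematic: real guideline models are larger, mix many
patterns, carry free-text conditions that the mini grammar will not parse
(every such condition surfaces in the post-editing report), and contain
data and temporal aspects that are out of scope here. Passing the trace
suite therefore shows that the per-pattern transformations preserve
control-flow behaviour, not that a full guideline can be compiled without
manual post-editing — condition formalization in particular remains a
human step by design.

## Problem sizes

The validation suite runs every (pattern, language) cell at `loop_bound` 2
and `max_steps` 64; fixtures have at most 3 branches / 7 tasks, for trace
sets between 1 and 90 traces per cell. The brute-force cross-check
enumerates at most 6! permutations per scenario. These sizes make the
whole acceptance run complete in seconds while still covering every
mapping rule and every matrix cell exhaustively.

## Known limitations

* Full BPMN 2.0 (pools, lanes, data objects, boundary events, timers,
  compensation) is out of scope; unsupported constructs error loudly.
* The Asbru XML dialect names the constructs (`subplans type="any-order"`,
  `wait-for`, filter/abort/complete conditions) without binding to a
  specific Asbru schema version; `--strict-schema` validates against a
  user-supplied XSD. The PROforma text dialect is this package's own
  stable syntax; targeting Tallis requires a syntax adaptation pass.
* Recognition requires structured input; unstructured models are rejected
  with a violation report, not approximated.
* Time annotations, intentions/effects, the full Asbru plan-state model,
  PROforma enquiries and argument weighting are not modelled.
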