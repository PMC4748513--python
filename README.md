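# cigflow

Clinical practice guidelines (CPGs) describe diagnostic and therapeutic
procedures in natural language; to drive decision-support systems they must
be re-authored in an executable *computer-interpretable guideline* (CIG)
language such as **Asbru** (hierarchies of plans with `sequentially` /
`parallel` / `any-order` bodies, `wait-for` expressions, and filter/abort/
complete conditions) or **PROforma** (networks of plans, actions and
decisions linked by scheduling constraints, with decision candidates
supported by arguments). That authoring step is slow and requires both
clinical and technical skill.

`cigflow` supports a pattern-and-transformation approach to this problem.
The recurring control structures of care processes — sequences, exclusive
and multiple choices, parallelism, loops, triggers, milestones,
cancellation, interleaving — are the *workflow control patterns* (#1–#43 of
the Russell / van der Aalst catalogue). Of these, 22 are relevant to
single-patient guideline care (19 found in real CPG text plus 3 of unknown
applicability, i.e. ~51 % of the catalogue); the rest concern multiple
concurrent task instances, multiple execution threads, or unstructured
models, which guideline processes do not need. A guideline fragment
modelled in implementation-neutral BPMN 2.0 using only these patterns can
then be compiled mechanically into each target language.

The package provides, for that relevant subset:

- **catalog** — the machine-readable suitability and implementability
  matrices (per pattern: relevant or not; per language: `+` directly
  implementable, `+/-` implementable via workarounds, `-` not
  implementable);
- **bpmn** — reader, writer and structuredness validation for the BPMN 2.0
  interchange subset the patterns need (a *structured* model is one where
  every split gateway has a matching same-kind join and split–join pairs
  nest properly);
- **fixtures** — a deterministic generator of the canonical BPMN model for
  every relevant pattern, plus structured compositions;
- **recognize** — single-entry/single-exit region decomposition and
  pattern labelling;
- **asbru** / **proforma** — the per-pattern emitters (a transient trigger
  cannot be expressed in Asbru; interleaved routing, interleaved parallel
  routing and critical section cannot be expressed in PROforma — those
  transformations refuse rather than emit a wrong model);
- **semantics** — the validation oracle: both emitted models compile onto
  one executable intermediate whose finite trace sets are enumerated
  exhaustively and compared against closed-form reference semantics per
  pattern.

## Worked example: the persistent trigger (#24)

A persistent trigger lets a task proceed in response to a signal that stays
active until consumed — e.g. *perform spirometry if a substantial increase
in symptoms is reported*. In BPMN it is modelled with a start message
event, a triggering task, and an intermediate message event guarding the
target task:

```sh
$ cig fixtures --pattern 24 --out .
$ cig transform pattern_24.bpmn --target proforma -o pattern_24.pf
$ cat pattern_24.pf
action :: 'action_A'
end action.

action :: 'action_B'
  schedule_constraint : completed(action_A)
  wait_condition : completed(trigger_action)
end action.

action :: 'trigger_action'
  trigger : external_request
end action.

plan :: 'fixture_p24'
  components : 'action_A', 'action_B', 'trigger_action'
end plan.
```

Note what the transformation did: the intermediate message event is *not*
materialized as a component; instead `action_B` keeps a scheduling
constraint on the nearest preceding non-event task (`action_A`, so it is
not disconnected from the flow) and receives a state trigger
(`wait_condition`) on completion of `trigger_action`, which itself carries
an event trigger for the external signal.

The emitted model is then validated by trace semantics:

```sh
$ cig validate-semantics --pattern 24 --target proforma
PASS: pattern #24 in proforma: 6 traces match the reference
```

The 6 traces are exactly the interleavings of `trigger_action` with the
`action_A → action_B` sequence in which the trigger completes before
`action_B` starts. The same loop runs for every implementable
pattern/language cell; for the inexpressible cells the emitter refuses:

```sh
$ cig transform pattern_40.bpmn --target proforma; echo $?
error: pattern #40 is not implementable in proforma (implementability matrix label '-')
4
```

Other subcommands: `cig catalog` (the matrices with counts), `cig validate`
(structuredness report), `cig detect` (pattern instances with role
bindings), `cig matrix-report`.

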