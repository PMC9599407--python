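# Synthetic fixture lexicon of student stress events (columns: dis ang sur fea joy sad).
# Phrases are English placeholders and stimulus vectors are hand-set; this file is a
# test fixture, not a validated clinical instrument.  Event 15 is a documented
# placeholder: the source checklist names 15 student events but enumerates 14.
event_id	phrase	weight	stim_dis	stim_ang	stim_sur	stim_fea	stim_joy	stim_sad
death_of_parent	passed away	1.0	-0.3	-0.4	-0.3	-0.6	-0.6	-0.9
parents_divorce	parents divorced	1.0	-0.3	-0.5	-0.3	-0.4	-0.4	-0.7
dismissal	got fired	1.0	-0.4	-0.6	-0.2	-0.5	-0.4	-0.5
family_serious_illness	gravely ill	1.0	-0.2	-0.3	-0.3	-0.7	-0.4	-0.6
lovelorn	broke up	1.0	-0.4	-0.5	-0.2	-0.3	-0.5	-0.7
outstanding_achievement	won the award	1.0	0.2	0.1	0.4	0.1	0.8	0.3
serious_illness_trauma	badly injured	1.0	-0.3	-0.4	-0.4	-0.7	-0.4	-0.6
begin_love	found a partner	1.0	0.2	0.1	0.3	0.1	0.7	0.3
disciplinary_action	disciplinary action	1.0	-0.5	-0.6	-0.2	-0.5	-0.4	-0.5
school_entry_setback	failed the entrance exam	1.0	-0.4	-0.5	-0.2	-0.5	-0.5	-0.7
join_party_league	joined the league	1.0	0.1	0.1	0.2	0.1	0.6	0.2
drop_out_of_school	drop out	1.0	-0.5	-0.7	-0.1	-0.4	-0.5	-0.5
failing_school_employment	failed my courses	1.0	-0.4	-0.5	-0.2	-0.5	-0.4	-0.6
learning_difficulty	learning difficulty	1.0	-0.3	-0.3	-0.1	-0.4	-0.3	-0.5
unspecified_event_15	overwhelmed by stress	1.0	-0.3	-0.3	-0.1	-0.4	-0.3	-0.4
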