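name,value,description
intercept,-1.515,Intercept
age,0.0263,Age
sex_female,0.1105,Sex is female (0 = Male; 1 = Female)
race_hispanic,-0.0819,Race is hispanic
race_black,-0.5597,Race is black
race_other,-0.9751,Race is other
child_badly_beaten_by_caregiver,-0.5603,"as child, badly beaten by parent/caregiver"
badly_beaten_by_partner,0.0504,badly beaten by spouse/romantic partner
badly_beaten_by_other,-0.3877,badly beaten by anyone else
mugged_or_threatened_with_weapon,0.1148,mugged/held up/threatened with weapon
ever_raped,-0.1614,ever raped (penetration occurred)
ever_sexually_assaulted,0.5993,ever sexually assaulted or molested
someone_close_died_unexpectedly,0.078,someone close died unexpectedly
close_person_extreme_trauma,0.4687,anyone close had extreme traumatic exper.
child_witnessed_serious_fights,0.4591,"as child, witnessed serious physical fights"
saw_badly_injured_or_dead,0.1683,saw person badly injured/killed/dead body
other_very_traumatic_event,-0.2237,ever experienced other very traumatic event
avoid_reminders_of_event,0.3664,purposely stay away things remind event
lost_interest_in_activities,-0.0581,lose interest in things used to enjoy
emotionally_distant,0.2516,feel emotionally distant/cut-off from people
trouble_feeling_love,0.1159,trouble feeling love/happiness toward others
no_reason_to_plan_future,0.64,feel no reason to plan for the future
trouble_sleeping_random_event,0.8654,trouble falling asleep during random event
easily_startled,0.1323,more easily startled by ordinary noises
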