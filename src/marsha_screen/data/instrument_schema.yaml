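# MARSHA victimization instrument schema.
#
# 34 past-year victimization items, each answered on a 4-category frequency
# scale (0 times / 1-3 times / 4-10 times / more than 10 times), grouped into
# the instrument's five subscales.  Only the three screener (MARSHA-C) items,
# the excluded high-prevalence item, and two monitoring behaviors are publicly
# documented item texts; the remaining item ids and texts are schematic
# stand-ins with the correct subscale structure (synthetic placeholders).
#
# "category" is the reporting taxonomy used for headline abuse-type
# prevalences (physical / sexual / emotional / technology); it is distinct
# from the five instrument subscales, and social-control items fall outside it.
screener_items: [int_yelled, sex_pressured_photo, soc_trapped]
excluded_from_screener: [soc_stopped_talking]
items:
  - {id: phys_pushed,            subscale: physical,        category: physical,   text: "They pushed, grabbed, or shoved me"}
  - {id: phys_slapped,           subscale: physical,        category: physical,   text: "They slapped me"}
  - {id: phys_hit,               subscale: physical,        category: physical,   text: "They hit or punched me"}
  - {id: phys_kicked,            subscale: physical,        category: physical,   text: "They kicked me"}
  - {id: phys_choked,            subscale: physical,        category: physical,   text: "They choked me"}
  - {id: phys_threw_object,      subscale: physical,        category: physical,   text: "They threw something at me that could hurt"}
  - {id: phys_pulled_hair,       subscale: physical,        category: physical,   text: "They pulled my hair"}
  - {id: phys_hurt_other,        subscale: physical,        category: physical,   text: "They physically hurt me in some other way"}
  - {id: sex_pressured_photo,    subscale: sexual,          category: technology, text: "They asked or pressured me for a nude or almost nude photo or video of me, when I did not want to give them one"}
  - {id: sex_shared_photo,       subscale: sexual,          category: sexual,     text: "They shared a sexual photo or video of me without my consent"}
  - {id: sex_forced_act,         subscale: sexual,          category: sexual,     text: "They made me do something sexual that I did not want to do"}
  - {id: sex_pressured_sex,      subscale: sexual,          category: sexual,     text: "They pressured me to have sex when I did not want to"}
  - {id: sex_unwanted_touch,     subscale: sexual,          category: sexual,     text: "They touched me sexually when I did not want them to"}
  - {id: sex_rumors,             subscale: sexual,          category: sexual,     text: "They spread sexual rumors about me"}
  - {id: priv_tracked_social,    subscale: privacy_control, category: technology, text: "They used social media or other apps to keep track of me and monitor where I was going or where I had been"}
  - {id: priv_looked_phone,      subscale: privacy_control, category: technology, text: "They looked through my phone or other device when I did not want them to"}
  - {id: priv_demanded_password, subscale: privacy_control, category: technology, text: "They demanded my passwords or account access"}
  - {id: priv_read_messages,     subscale: privacy_control, category: technology, text: "They read my private messages without permission"}
  - {id: priv_checked_location,  subscale: privacy_control, category: technology, text: "They made me share my location so they could check on me"}
  - {id: priv_posted_about_me,   subscale: privacy_control, category: technology, text: "They posted things about me online that I wanted kept private"}
  - {id: soc_trapped,            subscale: social_control,  category: null,       text: "They made me feel like I could not break up with them or get out of the relationship"}
  - {id: soc_stopped_talking,    subscale: social_control,  category: null,       text: "They stopped talking to me and I felt punished, hurt, or scared"}
  - {id: soc_jealous,            subscale: social_control,  category: null,       text: "They accused me of flirting or cheating when I had not"}
  - {id: soc_chose_friends,      subscale: social_control,  category: null,       text: "They told me who I could or could not spend time with"}
  - {id: soc_kept_from_family,   subscale: social_control,  category: null,       text: "They kept me from seeing my family or friends"}
  - {id: soc_controlled_clothes, subscale: social_control,  category: null,       text: "They told me what I could or could not wear"}
  - {id: soc_demanded_time,      subscale: social_control,  category: null,       text: "They demanded to know where I was at all times"}
  - {id: int_yelled,             subscale: intimidation,    category: emotional,  text: "They yelled, screamed or swore at me"}
  - {id: int_threatened_hurt,    subscale: intimidation,    category: emotional,  text: "They threatened to hurt me"}
  - {id: int_destroyed_property, subscale: intimidation,    category: emotional,  text: "They destroyed or threatened to destroy something I valued"}
  - {id: int_threatened_self,    subscale: intimidation,    category: emotional,  text: "They threatened to hurt themselves if I left"}
  - {id: int_humiliated,        subscale: intimidation,    category: emotional,  text: "They put me down or humiliated me in front of others"}
  - {id: int_insulted,          subscale: intimidation,    category: emotional,  text: "They insulted me or called me names"}
  - {id: int_scared_looks,      subscale: intimidation,    category: emotional,  text: "They scared me with looks or gestures"}
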