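# Hypothesised data-generating process for the daily active minutes of a pet
# dog.  One edge "parent -> child" per line; "name [latent]" marks a node as
# unobserved.  This graph is an editable modelling input, not ground truth:
# edit it and the adjustment sets and implied independences change with it.
#
# Structure encoded here:
#   - location type and owner age influence both breed-size choice and daily
#     activity, so they confound the dog-attribute -> activity relations;
#   - unhealthy diagnoses and injury are mediators of dog attributes, not
#     confounders, so they are not adjusted for;
#   - daily weather is a latent mediator of climate and season;
#   - environmental exposures (season, day type, owner age, location) have no
#     unblocked backdoor paths to activity.
weather [latent]
latitude -> climate
latitude -> active_minutes
climate -> weather
season -> weather
weather -> active_minutes
day_type -> active_minutes
owner_age -> active_minutes
owner_age -> breed_size
owner_age -> neuter_status
location_type -> active_minutes
location_type -> breed_size
dog_age -> active_minutes
dog_age -> unhealthy_diagnosis
dog_age -> injury
breed_size -> active_minutes
breed_size -> unhealthy_diagnosis
weight_status -> active_minutes
weight_status -> unhealthy_diagnosis
weight_status -> injury
neuter_status -> active_minutes
neuter_status -> weight_status
sex -> active_minutes
sex -> neuter_status
unhealthy_diagnosis -> active_minutes
injury -> active_minutes
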